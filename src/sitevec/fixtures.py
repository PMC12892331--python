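"""Synthetic structures with analytically known cavities.

These generators build hard-sphere "pockets" whose true first-surface
distances are known in closed form, so ray tracing, metrics, clustering and
pose screening can all be validated without any external structure files.

A cavity is a shell of identical atoms on (a hemisphere of) a sphere of
radius ``pocket_radius`` centred at the origin: every upward ray from the
origin first meets an atom surface at ``pocket_radius − atom_radius``, up to
the tiling granularity of the shell.  Atoms are placed on a Fibonacci lattice
(near-uniform coverage) and the generator reports its granularity — the
maximum extra depth a ray can reach by slipping between neighbouring atoms —
so tests can set tolerances programmatically rather than guessing.

All generators are pure functions of their arguments, including the seed.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np

from .structure_model import Atom, Structure

logger = logging.getLogger(__name__)

__all__ = ["make_cavity", "make_two_state_ensemble", "make_charged_patch",
           "fibonacci_sphere"]


def fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform unit vectors on the sphere (golden-angle lattice)."""
    i = np.arange(n, dtype=float)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    theta = golden * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _shell_points(pocket_radius: float, shell_density: float,
                  z_margin: float) -> np.ndarray:
    """Fibonacci-lattice points on the sphere with z >= -z_margin (in Å)."""
    n_total = max(int(np.ceil(shell_density * 4.0 * np.pi * pocket_radius**2)), 16)
    pts = fibonacci_sphere(n_total) * pocket_radius
    return pts[pts[:, 2] >= -z_margin]


def _granularity(centers: np.ndarray, pocket_radius: float,
                 atom_radius: float) -> float:
    """Measured tiling granularity of a realized shell.

    Traces a dense set of upward probe rays against the nearest shell atoms
    and returns the worst deviation of the first-surface distance from the
    ideal ``pocket_radius − atom_radius``, with a 25% safety margin for rays
    falling between probes.  Infinite when some probe ray passes through an
    open gap (shell too sparse to close).
    """
    from scipy.spatial import cKDTree

    n_probes = max(8 * len(centers), 2048)
    probes = fibonacci_sphere(n_probes)
    probes = probes[probes[:, 2] >= 0.0]
    tree = cKDTree(centers)
    k = min(8, len(centers))
    _, idx = tree.query(probes * pocket_radius, k=k)
    idx = np.atleast_2d(idx.T).T if idx.ndim == 1 else idx
    near = centers[idx]                                # (p, k, 3)
    b = np.einsum("pkj,pj->pk", near, probes)
    y2 = np.einsum("pkj,pkj->pk", near, near) - b**2
    disc = atom_radius**2 - y2
    hit = disc >= 0
    entry = np.where(hit, b - np.sqrt(np.maximum(disc, 0.0)), np.inf)
    first = entry.min(axis=1)
    if not np.isfinite(first).all():
        return float("inf")
    ideal = pocket_radius - atom_radius
    return 1.25 * float(np.abs(first - ideal).max()) + 1e-9


def make_cavity(pocket_radius: float = 8.0, atom_radius: float = 1.0,
                shell_density: float = 2.0, seed: int = 0,
                jitter_sd: float = 0.0,
                structure_id: str = "cavity") -> Structure:
    """Hemispherical shell cavity with known first-surface distance.

    Atoms of radius ``atom_radius`` (zero charge) tile the hemisphere shell
    of radius ``pocket_radius`` above the xy-plane; the shell extends
    slightly below the equator (by one atom radius) so equatorial rays are
    covered too.  Along any upward ray from the origin the first surface sits
    at ``pocket_radius − atom_radius`` within the reported granularity,
    stored in ``structure.meta["granularity"]``.
    """
    if not (pocket_radius > atom_radius > 0):
        raise ValueError("need pocket_radius > atom_radius > 0")
    if shell_density <= 0:
        raise ValueError("shell_density must be positive")
    pts = _shell_points(pocket_radius, shell_density, z_margin=atom_radius)
    rng = np.random.default_rng(seed)
    if jitter_sd > 0:
        pts = pts + rng.normal(0.0, jitter_sd, pts.shape)
    delta = _granularity(pts, pocket_radius, atom_radius)
    if not np.isfinite(delta):
        logger.warning("shell_density %.3g too low to close the shell "
                       "(probe rays escape through lattice gaps)", shell_density)
    atoms = [Atom(element="C", name="C", residue_name="CAV", residue_id=i + 1,
                  coordinates=p, vdw_radius=atom_radius, partial_charge=0.0)
             for i, p in enumerate(pts)]
    st = Structure(id=structure_id, atoms=atoms)
    st.meta["granularity"] = delta
    st.meta["pocket_radius"] = pocket_radius
    st.meta["atom_radius"] = atom_radius
    st.meta["expected_hit_length"] = pocket_radius - atom_radius
    return st


def make_two_state_ensemble(n_frames: int, state_radii: tuple[float, float] = (6.0, 10.0),
                            mix: float = 0.5, noise_sd: float = 0.05,
                            atom_radius: float = 1.0, shell_density: float = 2.0,
                            seed: int = 0,
                            system_id: str = "twostate"
                            ) -> tuple[list[Structure], np.ndarray]:
    """Ensemble of cavity frames drawn from two pocket-radius states.

    Each frame is a cavity whose pocket radius is one of ``state_radii``
    (state picked per-frame with probability ``mix`` for the first state) with
    seeded Gaussian coordinate noise of ``noise_sd`` Å.  Returns the frames
    and the ground-truth state labels (0/1).
    """
    if n_frames < 2:
        raise ValueError("n_frames must be at least 2")
    if not (0.0 < mix < 1.0):
        raise ValueError("mix must be in (0, 1)")
    rng = np.random.default_rng(seed)
    states = (rng.random(n_frames) >= mix).astype(int)  # 0 w.p. mix
    frames = []
    for k in range(n_frames):
        rho = state_radii[states[k]]
        frame = make_cavity(pocket_radius=rho, atom_radius=atom_radius,
                            shell_density=shell_density,
                            seed=int(rng.integers(2**31)),
                            jitter_sd=noise_sd,
                            structure_id=system_id)
        frame.frame_index = k
        frame.meta["state"] = int(states[k])
        frames.append(frame)
    return frames, states


def make_charged_patch(pocket_radius: float = 8.0, atom_radius: float = 1.0,
                       shell_density: float = 2.0, seed: int = 0,
                       patch_solid_angle: float = np.pi,
                       patch_charge: float = 0.2,
                       structure_id: str = "patched") -> Structure:
    """Cavity with a charged polar cap of the given solid angle.

    Atoms within the cap around +z (solid angle ``Ω = 2π(1 − cos θ)``) carry
    ``patch_charge``; the rest stay neutral.  Against the uncharged cavity of
    the same geometry, the charge RMSD has the closed form
    ``|patch_charge| · sqrt(fraction of rays inside the patch)``.
    """
    if not (0.0 <= patch_solid_angle <= 4.0 * np.pi):
        raise ValueError("patch_solid_angle must be in [0, 4π] sr")
    st = make_cavity(pocket_radius=pocket_radius, atom_radius=atom_radius,
                     shell_density=shell_density, seed=seed,
                     structure_id=structure_id)
    cos_theta = 1.0 - patch_solid_angle / (2.0 * np.pi)
    for a in st.atoms:
        r = np.linalg.norm(a.coordinates)
        if r > 0 and a.coordinates[2] / r >= cos_theta:
            a.partial_charge = patch_charge
    st.meta["patch_cos_theta"] = cos_theta
    return st
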