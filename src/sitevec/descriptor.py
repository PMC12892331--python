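"""Tracing binding-site vectors and ligand vectors.

Each scaffold direction defines a ray from the anchor.  For a *site*
descriptor the ray is truncated at the first van der Waals sphere it enters
(smallest entry distance over all non-excluded atoms) and carries that atom's
partial charge; a ray that meets nothing keeps the full scaffold length with
charge zero.  For a *ligand* descriptor the same ray is instead extended to
the farthest exit point from the ligand's atom spheres, encoding the ligand
envelope in the same indexed directions, so site and ligand vectors are
directly comparable per index.

Geometry per atom (Fig.-3-style construction): with ``a = |center − origin|``
and ``b = (center − origin)·direction``, the perpendicular offset is
``y = sqrt(a² − b²)``; the ray intersects the sphere iff ``y ≤ r``, with
entry/exit distances ``c = b ∓ sqrt(r² − y²)``.  Atoms whose entry distance is
non-positive (behind or containing the origin) are skipped for site tracing,
and ties on the entry distance go to the lowest atom index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .geometry import VectorScaffold
from .structure_model import Atom, Structure, DEFAULT_EXCLUDED_RESNAMES

logger = logging.getLogger(__name__)

__all__ = [
    "SiteDescriptor", "LigandDescriptor",
    "intersect_ray_sphere", "trace_site", "trace_ligand",
    "write_descriptor", "read_descriptor",
    "default_exclude",
]


@dataclass
class SiteDescriptor:
    """Per-vector first-surface lengths (Å) and hit-atom charges (e).

    Arrays are indexed like the scaffold's retained directions.  A vector
    with no hit has ``length == max_length``, ``charge == 0`` and
    ``hit_atom_index == -1``.
    """

    structure_id: str
    frame_index: int
    lengths: np.ndarray
    charges: np.ndarray
    hit_atom_index: np.ndarray

    def __len__(self) -> int:
        return len(self.lengths)


@dataclass
class LigandDescriptor:
    """Per-vector farthest-exit lengths over a ligand's atoms.

    ``lengths`` is 0 where the ray misses the ligand (``hit_mask`` False);
    ``charges`` holds the partial charge of the atom providing the farthest
    exit.
    """

    ligand_id: str
    lengths: np.ndarray
    charges: np.ndarray
    hit_mask: np.ndarray

    def __len__(self) -> int:
        return len(self.lengths)


def intersect_ray_sphere(direction, atom: Atom, origin=(0.0, 0.0, 0.0)
                         ) -> Optional[tuple[float, float]]:
    """Entry/exit distances of a ray against one atom sphere, or None.

    Returns ``None`` when the ray misses the sphere or the sphere lies
    entirely behind the origin (exit distance ≤ 0).
    """
    direction = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(direction) - 1.0) > 1e-6:
        raise ValueError("direction must be a unit vector")
    rel = atom.coordinates - np.asarray(origin, dtype=float)
    b = float(rel @ direction)
    y2 = float(rel @ rel) - b * b
    r2 = atom.vdw_radius**2
    if y2 > r2:
        return None
    half = np.sqrt(max(r2 - y2, 0.0))
    entry, exit_ = b - half, b + half
    if exit_ <= 0.0:
        return None
    return entry, exit_


def _entry_exit_matrix(directions: np.ndarray, centers: np.ndarray,
                       radii: np.ndarray, origin: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized entry/exit distances; NaN where a ray misses an atom.

    Shapes: directions (n,3), centers (m,3) -> (n,m) arrays.
    """
    rel = centers - origin                      # (m,3)
    b = directions @ rel.T                      # (n,m)
    a2 = np.einsum("ij,ij->i", rel, rel)        # (m,)
    disc = radii[None, :] ** 2 - (a2[None, :] - b**2)
    miss = disc < 0
    half = np.sqrt(np.where(miss, 0.0, disc))
    entry = np.where(miss, np.nan, b - half)
    exit_ = np.where(miss, np.nan, b + half)
    # sphere entirely behind the origin
    behind = exit_ <= 0
    entry[behind] = np.nan
    exit_[behind] = np.nan
    return entry, exit_


def default_exclude(atom: Atom) -> bool:
    """Default exclusion: heme plus waters and ions."""
    return atom.is_excluded or atom.residue_name.upper() in DEFAULT_EXCLUDED_RESNAMES


def trace_site(structure: Structure, scaffold: VectorScaffold,
               origin=(0.0, 0.0, 0.0),
               exclude: Optional[Callable[[Atom], bool]] = default_exclude
               ) -> SiteDescriptor:
    """Trace first-surface binding-site vectors through the scaffold.

    For each retained direction the winning atom is the non-excluded atom
    with the smallest positive entry distance not exceeding
    ``scaffold.max_length``; its entry distance becomes the vector length and
    its partial charge the vector charge.  Directions with no such atom keep
    ``max_length`` and charge 0.

    Raises a state error if radii were never assigned.
    """
    radii_all = structure.radii()
    if np.isnan(radii_all).any():
        raise RuntimeError(
            f"structure {structure.id!r} has unassigned vdW radii; "
            "call assign_radii first")

    if exclude is None:
        keep = np.arange(len(structure.atoms))
    else:
        keep = np.array([i for i, a in enumerate(structure.atoms)
                         if not exclude(a)], dtype=int)

    directions = scaffold.retained_directions
    n = len(directions)
    lengths = np.full(n, scaffold.max_length, dtype=float)
    charges = np.zeros(n, dtype=float)
    hit = np.full(n, -1, dtype=int)

    if len(keep) > 0:
        origin = np.asarray(origin, dtype=float)
        entry, _ = _entry_exit_matrix(directions, structure.coords()[keep],
                                      radii_all[keep], origin)
        # a positive entry within range is required for a site hit
        entry[~(entry > 0) | (entry > scaffold.max_length)] = np.nan
        valid_any = ~np.isnan(entry).all(axis=1)
        if valid_any.any():
            # nanargmin keeps the lowest atom index on exact ties
            winners = np.full(n, -1, dtype=int)
            sub = np.nan_to_num(entry[valid_any], nan=np.inf)
            winners[valid_any] = np.argmin(sub, axis=1)
            rows = np.flatnonzero(valid_any)
            cols = winners[rows]
            lengths[rows] = entry[rows, cols]
            charges[rows] = structure.charges()[keep][cols]
            hit[rows] = keep[cols]
    return SiteDescriptor(structure_id=structure.id,
                          frame_index=structure.frame_index,
                          lengths=lengths, charges=charges,
                          hit_atom_index=hit)


def trace_ligand(ligand: Structure, scaffold: VectorScaffold,
                 origin=(0.0, 0.0, 0.0)) -> LigandDescriptor:
    """Trace ligand vectors: farthest sphere-exit point per direction.

    Lengths are clamped to ``scaffold.max_length``; rays that meet no ligand
    atom get length 0 and ``hit_mask`` False.
    """
    radii_all = ligand.radii()
    if np.isnan(radii_all).any():
        raise RuntimeError(
            f"ligand {ligand.id!r} has unassigned vdW radii; "
            "call assign_radii first")

    directions = scaffold.retained_directions
    n = len(directions)
    origin = np.asarray(origin, dtype=float)
    _, exit_ = _entry_exit_matrix(directions, ligand.coords(), radii_all, origin)
    lengths = np.zeros(n, dtype=float)
    charges = np.zeros(n, dtype=float)
    hit_mask = ~np.isnan(exit_).all(axis=1)
    if hit_mask.any():
        sub = np.nan_to_num(exit_[hit_mask], nan=-np.inf)
        cols = np.argmax(sub, axis=1)
        rows = np.flatnonzero(hit_mask)
        lengths[rows] = np.minimum(exit_[rows, cols], scaffold.max_length)
        charges[rows] = ligand.charges()[cols]
    return LigandDescriptor(ligand_id=ligand.id, lengths=lengths,
                            charges=charges, hit_mask=hit_mask)


# ---------------------------------------------------------------------------
# Descriptor I/O
# ---------------------------------------------------------------------------

def write_descriptor(descriptor, scaffold: VectorScaffold, path) -> None:
    """Write a site or ligand descriptor as TSV.

    Columns: vector_index, x, y, z, length_A, charge_e, hit_atom.  The
    vector index refers to the full-sphere scaffold ordering.
    """
    idx = scaffold.retained_indices
    dirs = scaffold.retained_directions
    if isinstance(descriptor, SiteDescriptor):
        hit = descriptor.hit_atom_index
    else:
        hit = np.where(descriptor.hit_mask, 1, -1)
    df = pd.DataFrame({
        "vector_index": idx,
        "x": dirs[:, 0], "y": dirs[:, 1], "z": dirs[:, 2],
        "length_A": descriptor.lengths,
        "charge_e": descriptor.charges,
        "hit_atom": hit,
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_descriptor(path, structure_id: Optional[str] = None,
                    frame_index: int = 0) -> SiteDescriptor:
    """Read a site descriptor TSV written by :func:`write_descriptor`."""
    df = pd.read_csv(path, sep="\t")
    return SiteDescriptor(
        structure_id=structure_id or str(path),
        frame_index=frame_index,
        lengths=df["length_A"].to_numpy(dtype=float),
        charges=df["charge_e"].to_numpy(dtype=float),
        hit_atom_index=df["hit_atom"].to_numpy(dtype=int),
    )
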