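"""Geodesic vector scaffold.

A binding-site vector set is built from a class-I geodesic subdivision of the
icosahedron: each edge is split into ``frequency`` segments, every face is
triangulated, the vertices are projected radially onto the unit sphere, and
duplicated vertices on shared edges are removed.  The resulting unit
directions, together with a maximum ray length (the initial sphere radius),
form the :class:`VectorScaffold`.  The full sphere carries exactly
``10 * frequency**2 + 2`` directions; restricting to the hemisphere above an
anchor plane keeps only the rays that probe the functional side of the pocket.

The icosahedron uses the golden-ratio vertex set (permutations of
``(0, ±1, ±φ)``, normalized), so the +z axis bisects an edge.  With this
orientation a frequency-7 sphere places 28 vertices exactly on the equator,
and the inclusive hemisphere rule (``dot(u, n) >= 0``) retains 260 of the 492
directions.  The orientation and the equator-inclusive rule are frozen package
defaults so descriptor indices are reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "VectorScaffold",
    "build_scaffold",
    "restrict_hemisphere",
    "write_scaffold",
    "read_scaffold",
    "DEFAULT_FREQUENCY",
    "DEFAULT_MAX_LENGTH",
    "EQUATOR_EPS",
]

#: Edge subdivision frequency used throughout the package (492 directions).
DEFAULT_FREQUENCY = 7
#: Initial sphere radius in Å; rays that hit nothing keep this length.
DEFAULT_MAX_LENGTH = 20.0
#: Tolerance for the equator-inclusive hemisphere rule (absorbs float noise
#: on directions that sit exactly in the anchor plane).
EQUATOR_EPS = 1e-9

_PHI = (1.0 + np.sqrt(5.0)) / 2.0

# Golden-ratio icosahedron: 12 vertices, +z bisects the (0,1,φ)-(0,-1,φ) edge.
_ICO_VERTICES = np.array(
    [
        (0, 1, _PHI), (0, -1, _PHI), (0, 1, -_PHI), (0, -1, -_PHI),
        (1, _PHI, 0), (-1, _PHI, 0), (1, -_PHI, 0), (-1, -_PHI, 0),
        (_PHI, 0, 1), (-_PHI, 0, 1), (_PHI, 0, -1), (-_PHI, 0, -1),
    ],
    dtype=float,
) / np.sqrt(1.0 + _PHI**2)

# 20 faces, indices into _ICO_VERTICES (consistent outward orientation is not
# needed: vertices are pooled and deduplicated).
_ICO_FACES = np.array(
    [
        (0, 1, 8), (0, 1, 9), (0, 4, 5), (0, 4, 8), (0, 5, 9),
        (1, 6, 7), (1, 6, 8), (1, 7, 9), (2, 3, 10), (2, 3, 11),
        (2, 4, 5), (2, 4, 10), (2, 5, 11), (3, 6, 7), (3, 6, 10),
        (3, 7, 11), (4, 8, 10), (5, 9, 11), (6, 8, 10), (7, 9, 11),
    ]
)


@dataclass(frozen=True)
class VectorScaffold:
    """Indexed unit directions of a geodesic sphere with a maximum ray length.

    Parameters
    ----------
    directions
        ``(n, 3)`` array of unit vectors in canonical order
        (descending z, then azimuth).
    max_length
        Sphere radius R in Å; the length assigned to rays with no surface hit.
    frequency
        Class-I subdivision frequency f; the full sphere has ``10 f**2 + 2``
        directions.
    hemisphere_mask
        Optional boolean array marking retained directions.  ``None`` means
        the full sphere.  Indexing of ``directions`` never changes, so masked
        descriptors from different structures stay comparable.
    """

    directions: np.ndarray
    max_length: float
    frequency: int
    hemisphere_mask: Optional[np.ndarray] = field(default=None)

    @property
    def n_directions(self) -> int:
        """Number of directions on the full sphere."""
        return len(self.directions)

    @property
    def retained_indices(self) -> np.ndarray:
        """Indices of directions kept by the hemisphere mask (all if unmasked)."""
        if self.hemisphere_mask is None:
            return np.arange(self.n_directions)
        return np.flatnonzero(self.hemisphere_mask)

    @property
    def retained_directions(self) -> np.ndarray:
        return self.directions[self.retained_indices]

    @property
    def n_retained(self) -> int:
        return len(self.retained_indices)


def _canonical_order(points: np.ndarray) -> np.ndarray:
    """Sort unit vectors by descending z, then azimuth in [0, 2π)."""
    az = np.mod(np.arctan2(points[:, 1], points[:, 0]), 2.0 * np.pi)
    order = np.lexsort((az, -points[:, 2]))
    return points[order]


def build_scaffold(frequency: int = DEFAULT_FREQUENCY,
                   max_length: float = DEFAULT_MAX_LENGTH) -> VectorScaffold:
    """Build the full-sphere geodesic scaffold.

    Each icosahedron face with corners A, B, C is subdivided into the lattice
    ``(i*A + j*B + k*C)/f`` with ``i + j + k = f``; every lattice point is
    projected radially onto the unit sphere and edge/vertex duplicates are
    removed by rounding coordinates to 1e-8 before hashing.

    Parameters
    ----------
    frequency
        Positive integer edge subdivision frequency.
    max_length
        Positive sphere radius in Å.

    Returns
    -------
    VectorScaffold
        Scaffold with exactly ``10 * frequency**2 + 2`` unit directions in
        canonical order, no hemisphere mask.
    """
    if not isinstance(frequency, (int, np.integer)) or frequency < 1:
        raise ValueError(f"frequency must be a positive integer, got {frequency!r}")
    if not np.isfinite(max_length) or max_length <= 0:
        raise ValueError(f"max_length must be positive, got {max_length!r}")

    f = int(frequency)
    pts = []
    for ia, ib, ic in _ICO_FACES:
        a, b, c = _ICO_VERTICES[ia], _ICO_VERTICES[ib], _ICO_VERTICES[ic]
        for i in range(f + 1):
            for j in range(f + 1 - i):
                k = f - i - j
                p = (i * a + j * b + k * c) / f
                pts.append(p / np.linalg.norm(p))
    pts = np.asarray(pts)
    # edge-shared lattice points are generated once per adjacent face
    _, keep = np.unique(np.round(pts, 8), axis=0, return_index=True)
    directions = _canonical_order(pts[np.sort(keep)])
    expected = 10 * f * f + 2
    assert len(directions) == expected, (len(directions), expected)
    return VectorScaffold(directions=directions, max_length=float(max_length),
                          frequency=f)


def restrict_hemisphere(scaffold: VectorScaffold,
                        plane_normal=(0.0, 0.0, 1.0),
                        inclusion_rule: str = "inclusive") -> VectorScaffold:
    """Mask the scaffold to the hemisphere on the ``plane_normal`` side.

    Parameters
    ----------
    scaffold
        A built scaffold (mask state is ignored; the rule is re-applied to the
        full direction set, which makes the operation idempotent).
    plane_normal
        Normal of the anchor plane through the origin (normalized internally).
    inclusion_rule
        ``"inclusive"`` (default) keeps directions with
        ``dot(u, n) >= -EQUATOR_EPS``, i.e. the open hemisphere plus the
        equator; with the default frequency-7 scaffold and the +z normal this
        retains 260 directions.  ``"strict"`` keeps ``dot(u, n) > EQUATOR_EPS``
        only.  ``"all"`` keeps every direction.

    Returns
    -------
    VectorScaffold
        Same directions and order, with ``hemisphere_mask`` set.
    """
    normal = np.asarray(plane_normal, dtype=float)
    norm = np.linalg.norm(normal)
    if not np.isfinite(norm) or norm < 1e-12:
        raise ValueError("plane_normal must be a nonzero 3-vector")
    normal = normal / norm

    dots = scaffold.directions @ normal
    if inclusion_rule == "inclusive":
        mask = dots >= -EQUATOR_EPS
    elif inclusion_rule == "strict":
        mask = dots > EQUATOR_EPS
    elif inclusion_rule == "all":
        mask = np.ones(scaffold.n_directions, dtype=bool)
    else:
        raise ValueError(f"unknown inclusion_rule {inclusion_rule!r}; "
                         "expected 'inclusive', 'strict' or 'all'")
    return VectorScaffold(directions=scaffold.directions,
                          max_length=scaffold.max_length,
                          frequency=scaffold.frequency,
                          hemisphere_mask=mask)


def write_scaffold(scaffold: VectorScaffold, path) -> None:
    """Export as TSV: index, x, y, z, max_length, in_hemisphere (1 header line)."""
    mask = (scaffold.hemisphere_mask
            if scaffold.hemisphere_mask is not None
            else np.ones(scaffold.n_directions, dtype=bool))
    with open(path, "w") as fh:
        fh.write("index\tx\ty\tz\tmax_length\tin_hemisphere\n")
        for i, (d, m) in enumerate(zip(scaffold.directions, mask)):
            fh.write(f"{i}\t{d[0]:.12f}\t{d[1]:.12f}\t{d[2]:.12f}\t"
                     f"{scaffold.max_length:g}\t{int(m)}\n")


def read_scaffold(path) -> VectorScaffold:
    """Read a scaffold written by :func:`write_scaffold`.

    The frequency is recovered from the direction count via ``10 f**2 + 2``.
    """
    data = np.loadtxt(path, skiprows=1)
    data = np.atleast_2d(data)
    directions = data[:, 1:4]
    max_length = float(data[0, 4])
    mask = data[:, 5].astype(bool)
    n = len(directions)
    f = int(round(np.sqrt((n - 2) / 10)))
    if 10 * f * f + 2 != n:
        raise ValueError(f"direction count {n} is not of the form 10 f**2 + 2")
    return VectorScaffold(directions=directions, max_length=max_length,
                          frequency=f,
                          hemisphere_mask=None if mask.all() else mask)
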