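"""Pocket similarity metrics and ensemble-weighted comparison.

Two descriptors on the same scaffold are compared vector index by vector
index.  Three root-mean-square metrics are defined over the N retained
vectors:

* shape:      ``RMSD_s  = sqrt( (1/N) Σ_k (l_k,a − l_k,b)² )``        [Å]
* charge:     ``RMSD_c  = sqrt( (1/N) Σ_k (q_k,a − q_k,b)² )``        [e]
* combined:   ``RMSD_sc = sqrt( (1/N) [ w_s Σ (Δl_k/σ_l)² + w_c Σ (Δq_k/σ_q)² ] )``

σ_l and σ_q normalize lengths and charges to a common unitless scale (the
means cancel in the difference and are kept only for reporting).  The weights
obey ``w_c = (1+d)·w_s`` with ``(w_s+w_c)/2 = 1``, i.e. ``w_s = 2/(2+d)`` and
``w_c = 2(1+d)/(2+d)``: ``d < 0`` emphasizes shape, ``d > 0`` charge, and
``d = 0`` gives the plain normalized sum ``w_s = w_c = 1``.

For conformational ensembles summarized by exemplars with frame weights
``n_i`` (``Σ n_i = N_frames``), the inter-system distance is the
weight-averaged sum over exemplar pairs::

    RMSD_AB = Σ_{i∈A} Σ_{j∈B} RMSD_ij · (n_i/N_A) · (n_j/N_B)

so exemplars representing larger fractions of the ensemble contribute
proportionally more.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .descriptor import SiteDescriptor

__all__ = [
    "SimilarityParams", "DistanceMatrix", "EnsembleSummary",
    "weights_from_d", "rmsd_shape", "rmsd_charge", "rmsd_combined",
    "compute_normalizers", "pairwise_matrix", "ensemble_rmsd",
    "ensemble_matrix", "write_matrix", "read_matrix",
    "DegenerateNormalizerError",
]


class DegenerateNormalizerError(ValueError):
    """Pooled values are constant; a standard deviation of 0 cannot normalize."""


def weights_from_d(d: float) -> tuple[float, float]:
    """Shape/charge weights (w_s, w_c) from the tuning parameter d.

    ``w_s = 2/(2+d)``, ``w_c = 2(1+d)/(2+d)``; both positive for ``d > -1``.
    """
    if not np.isfinite(d) or d <= -1.0:
        raise ValueError(f"d must be finite and > -1, got {d!r}")
    w_s = 2.0 / (2.0 + d)
    return w_s, (1.0 + d) * w_s


@dataclass(frozen=True)
class SimilarityParams:
    """Metric selection and tuning.

    mode
        ``"shape"``, ``"charge"`` or ``"combined"``.
    d
        Shape/charge tuning parameter (combined mode), ``d > -1``.
    sigma_l, sigma_q
        Normalizers in Å and e (required for combined mode); typically from
        :func:`compute_normalizers` over the comparison set, or set to
        published dataset constants.
    """

    mode: str = "combined"
    d: float = 0.0
    sigma_l: Optional[float] = None
    sigma_q: Optional[float] = None

    def __post_init__(self):
        if self.mode not in ("shape", "charge", "combined"):
            raise ValueError(f"unknown mode {self.mode!r}")
        weights_from_d(self.d)  # validates the domain
        if self.mode == "combined":
            if self.sigma_l is None or self.sigma_q is None:
                raise ValueError("combined mode requires sigma_l and sigma_q")
            if self.sigma_l <= 0 or self.sigma_q <= 0:
                raise ValueError("sigma_l and sigma_q must be positive")

    @property
    def weights(self) -> tuple[float, float]:
        return weights_from_d(self.d)


def _check_compatible(a: SiteDescriptor, b: SiteDescriptor) -> None:
    if len(a.lengths) != len(b.lengths):
        raise ValueError(
            f"descriptor sizes differ ({len(a.lengths)} vs {len(b.lengths)}); "
            "descriptors must come from the same scaffold")


def rmsd_shape(a: SiteDescriptor, b: SiteDescriptor) -> float:
    """Root-mean-square per-vector length difference, Å."""
    _check_compatible(a, b)
    return float(np.sqrt(np.mean((a.lengths - b.lengths) ** 2)))


def rmsd_charge(a: SiteDescriptor, b: SiteDescriptor) -> float:
    """Root-mean-square per-vector charge difference, e."""
    _check_compatible(a, b)
    return float(np.sqrt(np.mean((a.charges - b.charges) ** 2)))


def rmsd_combined(a: SiteDescriptor, b: SiteDescriptor,
                  params: SimilarityParams) -> float:
    """Weighted, normalized shape+charge RMSD (dimensionless)."""
    _check_compatible(a, b)
    if params.sigma_l is None or params.sigma_q is None:
        raise ValueError("combined metric requires sigma_l and sigma_q")
    if params.sigma_l <= 0 or params.sigma_q <= 0:
        raise ValueError("sigma_l and sigma_q must be positive")
    w_s, w_c = params.weights
    n = len(a.lengths)
    s = np.sum(((a.lengths - b.lengths) / params.sigma_l) ** 2)
    c = np.sum(((a.charges - b.charges) / params.sigma_q) ** 2)
    return float(np.sqrt((w_s * s + w_c * c) / n))


def metric(a: SiteDescriptor, b: SiteDescriptor,
           params: SimilarityParams) -> float:
    """Dispatch on ``params.mode``."""
    if params.mode == "shape":
        return rmsd_shape(a, b)
    if params.mode == "charge":
        return rmsd_charge(a, b)
    return rmsd_combined(a, b, params)


def compute_normalizers(descriptors: Sequence[SiteDescriptor]
                        ) -> tuple[float, float, float, float]:
    """Pooled (σ_l, σ_q, mean_l, mean_q) over all vectors of all descriptors.

    Population standard deviation (ddof=0).  The means cancel in the metric
    and are returned for reporting only.
    """
    if len(descriptors) < 1:
        raise ValueError("need at least one descriptor")
    lengths = np.concatenate([d.lengths for d in descriptors])
    charges = np.concatenate([d.charges for d in descriptors])
    sigma_l = float(np.std(lengths))
    sigma_q = float(np.std(charges))
    if sigma_l == 0.0:
        raise DegenerateNormalizerError("all pooled vector lengths are equal")
    if sigma_q == 0.0:
        raise DegenerateNormalizerError("all pooled vector charges are equal")
    return sigma_l, sigma_q, float(np.mean(lengths)), float(np.mean(charges))


@dataclass(frozen=True)
class DistanceMatrix:
    """Labelled symmetric nonnegative distance matrix with zero diagonal."""

    labels: tuple
    values: np.ndarray

    def __post_init__(self):
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValueError("matrix must be square and match the labels")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-9):
            raise ValueError("matrix diagonal must be zero")
        if (v < -1e-12).any():
            raise ValueError("matrix must be nonnegative")

    def __len__(self) -> int:
        return len(self.labels)


def pairwise_matrix(descriptors: Sequence[SiteDescriptor],
                    params: SimilarityParams,
                    labels: Optional[Sequence[str]] = None) -> DistanceMatrix:
    """All-pairs distance matrix under the selected metric."""
    n = len(descriptors)
    if labels is None:
        labels = [f"{d.structure_id}:{d.frame_index}" for d in descriptors]
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = metric(descriptors[i], descriptors[j],
                                                 params)
    return DistanceMatrix(labels=tuple(labels), values=values)


@dataclass
class EnsembleSummary:
    """Exemplar descriptors of one system with their frame weights."""

    system_id: str
    exemplars: list
    weights: np.ndarray
    total: int

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=int)
        if len(self.weights) != len(self.exemplars):
            raise ValueError("one weight per exemplar required")
        if (self.weights <= 0).any():
            raise ValueError("weights must be positive")
        if int(self.weights.sum()) != int(self.total):
            raise ValueError(
                f"weights sum to {self.weights.sum()}, expected total {self.total}")


def ensemble_rmsd(a: EnsembleSummary, b: EnsembleSummary,
                  params: SimilarityParams) -> float:
    """Frame-fraction-weighted RMSD between two exemplar ensembles."""
    wa = a.weights / a.total
    wb = b.weights / b.total
    out = 0.0
    for da, fa in zip(a.exemplars, wa):
        for db, fb in zip(b.exemplars, wb):
            out += metric(da, db, params) * fa * fb
    return float(out)


def ensemble_matrix(ensembles: Sequence[EnsembleSummary],
                    params: SimilarityParams) -> DistanceMatrix:
    """All-pairs ensemble-weighted distance matrix between systems.

    The diagonal is set to zero by convention (the self-term of the weighted
    sum is not a distance).
    """
    n = len(ensembles)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = ensemble_rmsd(ensembles[i],
                                                        ensembles[j], params)
    return DistanceMatrix(labels=tuple(e.system_id for e in ensembles),
                          values=values)


def write_matrix(matrix: DistanceMatrix, path) -> None:
    """Square TSV with the labels as header row and first column."""
    df = pd.DataFrame(matrix.values, index=list(matrix.labels),
                      columns=list(matrix.labels))
    df.to_csv(path, sep="\t", float_format="%.9g")


def read_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy(dtype=float)
    values = (values + values.T) / 2.0  # absorb round-trip rounding
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(labels=tuple(df.index), values=values)
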