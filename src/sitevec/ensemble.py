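"""Clustering of conformations and hierarchical similarity trees.

Conformational ensembles are reduced to exemplars by Affinity Propagation
(AP) on a precomputed similarity matrix (the negated distance matrix), either
over pocket descriptors or over backbone atom-positional RMSD.  Each exemplar
carries the number of frames assigned to it, so downstream comparisons can
weight exemplars by the fraction of the ensemble they represent.

A second, joint AP round pools the exemplars of several systems, clusters
them on the combined descriptor metric, and propagates the first-round frame
weights into a population table: the fraction of each system's frames landing
in each joint cluster.

Average-linkage (UPGMA-style) trees over any distance matrix are built with
scipy's hierarchical clustering and exported as Newick with branch lengths
from merge heights.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.cluster import AffinityPropagation
from sklearn.exceptions import ConvergenceWarning

from .similarity import (DistanceMatrix, EnsembleSummary, SimilarityParams,
                         pairwise_matrix)
from .structure_model import Structure, superpose

logger = logging.getLogger(__name__)

__all__ = [
    "APParams", "ClusterAssignment", "PopulationTable", "SimilarityTree",
    "cluster_descriptors", "cluster_backbone", "summarize_ensemble",
    "joint_recluster", "build_tree",
    "write_assignment", "write_population_table",
]


@dataclass(frozen=True)
class APParams:
    """Affinity Propagation settings.

    Similarities are the negated distances.  ``preference=None`` uses the
    mean off-diagonal similarity.  (scikit-learn's own default is the median
    of the full matrix, but with negated-distance similarities the zero
    self-similarity diagonal drags that median upward and tight, well
    separated groups get oversplit; the off-diagonal mean is scale-aware and
    behaves well from a handful of pooled exemplars up to full ensembles.)
    """

    damping: float = 0.9
    preference: Optional[float] = None
    seed: int = 0
    max_iter: int = 1000
    convergence_iter: int = 15


@dataclass
class ClusterAssignment:
    """Flat clustering with exemplars and per-cluster item counts."""

    labels: np.ndarray
    exemplar_indices: np.ndarray
    weights: np.ndarray
    converged: bool = True

    @property
    def n_clusters(self) -> int:
        return len(self.exemplar_indices)

    def __post_init__(self):
        if int(self.weights.sum()) != len(self.labels):
            raise ValueError("cluster weights must sum to the item count")


@dataclass
class PopulationTable:
    """Fraction of each system's frames assigned to each joint cluster."""

    systems: tuple
    clusters: tuple
    values: np.ndarray  # rows: systems, columns: clusters; each row sums to 1

    def __post_init__(self):
        sums = self.values.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError(f"population rows must sum to 1, got {sums}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.systems),
                            columns=list(self.clusters))


def cluster_descriptors(matrix: DistanceMatrix,
                        ap_params: APParams = APParams()) -> ClusterAssignment:
    """Affinity Propagation over a descriptor distance matrix.

    The similarity fed to AP is the negated distance.  Items at exactly zero
    distance are collapsed to a single representative first (message passing
    is ill-defined under exact duplicates: the tied messages make every copy
    its own exemplar) and re-expanded afterwards.  Non-convergence is logged
    and the best-iterate result returned flagged ``converged=False``; if AP
    yields no exemplars at all, every item is assigned to the medoid.
    """
    n = len(matrix)
    values = matrix.values

    # collapse exact duplicates (connected components of the d == 0 graph)
    from scipy.sparse.csgraph import connected_components
    n_comp, comp = connected_components(values <= 1e-12, directed=False)
    reps = np.array([np.flatnonzero(comp == c)[0] for c in range(n_comp)])

    if n_comp == 1:
        return ClusterAssignment(labels=np.zeros(n, dtype=int),
                                 exemplar_indices=reps[:1],
                                 weights=np.array([n], dtype=int))

    reduced = values[np.ix_(reps, reps)]
    similarity = -reduced
    preference = ap_params.preference
    if preference is None:
        off_diag = similarity[~np.eye(n_comp, dtype=bool)]
        preference = float(off_diag.mean())
    ap = AffinityPropagation(
        affinity="precomputed", damping=ap_params.damping,
        preference=preference, max_iter=ap_params.max_iter,
        convergence_iter=ap_params.convergence_iter,
        random_state=ap_params.seed)
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            ap.fit(similarity)
        except ConvergenceWarning:
            converged = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                ap.fit(similarity)
            logger.warning("Affinity Propagation did not converge after %d "
                           "iterations; returning best iterate",
                           ap_params.max_iter)

    red_labels = ap.labels_
    red_exemplars = ap.cluster_centers_indices_
    if (red_exemplars is None or len(np.atleast_1d(red_exemplars)) == 0
            or (np.asarray(red_labels) < 0).any()):
        # degenerate outcome: fall back to a single cluster at the medoid
        medoid = int(np.argmin(reduced.sum(axis=0)))
        red_labels = np.zeros(n_comp, dtype=int)
        red_exemplars = np.array([medoid])
        converged = False

    labels = np.asarray(red_labels, dtype=int)[comp]
    exemplars = reps[np.asarray(red_exemplars, dtype=int)]
    weights = np.bincount(labels, minlength=len(exemplars))
    return ClusterAssignment(labels=labels,
                             exemplar_indices=np.asarray(exemplars, dtype=int),
                             weights=weights.astype(int), converged=converged)


def cluster_backbone(frames: Sequence[Structure], selection=None,
                     ap_params: APParams = APParams()
                     ) -> tuple[ClusterAssignment, DistanceMatrix]:
    """Cluster frames on pairwise backbone superposition RMSD.

    Every pair is superposed over the selection (default backbone N/CA/C/O)
    and the minimized RMSD fills a distance matrix that is clustered as in
    :func:`cluster_descriptors`.
    """
    n = len(frames)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, rmsd = superpose(frames[i], frames[j], selection)
            values[i, j] = values[j, i] = rmsd
    matrix = DistanceMatrix(
        labels=tuple(f"{f.id}:{f.frame_index}" for f in frames), values=values)
    return cluster_descriptors(matrix, ap_params), matrix


def summarize_ensemble(system_id: str, descriptors: Sequence,
                       assignment: ClusterAssignment) -> EnsembleSummary:
    """Build an :class:`EnsembleSummary` from a first-round clustering."""
    exemplars = [descriptors[i] for i in assignment.exemplar_indices]
    return EnsembleSummary(system_id=system_id, exemplars=exemplars,
                           weights=assignment.weights,
                           total=int(assignment.weights.sum()))


def joint_recluster(ensembles: Sequence[EnsembleSummary],
                    params: SimilarityParams,
                    ap_params: APParams = APParams()
                    ) -> tuple[ClusterAssignment, PopulationTable]:
    """Second clustering round over the pooled exemplars of all systems.

    The pooled exemplars are clustered on the descriptor metric; each
    system's first-round frame weights are summed per joint cluster and
    normalized by the system's total frame count.
    """
    pooled = []
    owners = []
    pooled_weights = []
    for e in ensembles:
        for d, w in zip(e.exemplars, e.weights):
            pooled.append(d)
            owners.append(e.system_id)
            pooled_weights.append(int(w))
    matrix = pairwise_matrix(pooled, params,
                             labels=[f"{o}:{k}" for k, o in enumerate(owners)])
    assignment = cluster_descriptors(matrix, ap_params)

    systems = tuple(e.system_id for e in ensembles)
    n_clusters = assignment.n_clusters
    counts = np.zeros((len(systems), n_clusters), dtype=float)
    sys_index = {s: i for i, s in enumerate(systems)}
    for owner, w, lab in zip(owners, pooled_weights, assignment.labels):
        counts[sys_index[owner], lab] += w
    totals = np.array([e.total for e in ensembles], dtype=float)
    table = PopulationTable(systems=systems,
                            clusters=tuple(range(n_clusters)),
                            values=counts / totals[:, None])
    return assignment, table


# ---------------------------------------------------------------------------
# Average-linkage trees
# ---------------------------------------------------------------------------

@dataclass
class SimilarityTree:
    """Average-linkage tree over a distance matrix's labels."""

    labels: tuple
    linkage: np.ndarray  # scipy linkage matrix

    def cophenetic(self) -> np.ndarray:
        """Cophenetic distance matrix in label order."""
        return squareform(hierarchy.cophenet(self.linkage))

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        root = hierarchy.to_tree(self.linkage)

        def render(node, parent_height: float) -> str:
            if node.is_leaf():
                return f"{self.labels[node.id]}:{parent_height:.9g}"
            left = render(node.get_left(), node.dist)
            right = render(node.get_right(), node.dist)
            return f"({left},{right}):{parent_height - node.dist:.9g}"

        left = render(root.get_left(), root.dist)
        right = render(root.get_right(), root.dist)
        return f"({left},{right});"


def build_tree(matrix: DistanceMatrix) -> SimilarityTree:
    """Average-linkage (UPGMA-style) agglomerative tree over the labels.

    Branch lengths derive from the merge heights; for an ultrametric input
    the cophenetic distances reproduce the input exactly.
    """
    values = matrix.values
    if np.isnan(values).any() or (values < 0).any():
        raise ValueError("distance matrix must be finite and nonnegative")
    if len(matrix) < 2:
        raise ValueError("need at least 2 labels to build a tree")
    condensed = squareform(values, checks=False)
    linkage = hierarchy.linkage(condensed, method="average")
    return SimilarityTree(labels=tuple(matrix.labels), linkage=linkage)


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

def write_assignment(assignment: ClusterAssignment, labels: Sequence[str],
                     path) -> None:
    """TSV: item_id, cluster, is_exemplar, weight (of the item's cluster)."""
    ex = set(assignment.exemplar_indices.tolist())
    df = pd.DataFrame({
        "item_id": list(labels),
        "cluster": assignment.labels,
        "is_exemplar": [int(i in ex) for i in range(len(labels))],
        "weight": assignment.weights[assignment.labels],
    })
    df.to_csv(path, sep="\t", index=False)


def write_population_table(table: PopulationTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", float_format="%.6f")
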