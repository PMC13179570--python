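"""Mean-scaling normalization, SVD reduction, state clustering, 2D embedding.

The normalization is a per-batch per-gene multiplicative alignment: after
depth scaling and log1p, each batch's detected-cell mean for a gene is
scaled onto the pooled detected-cell mean (factor clamped to [0.1, 10]).
This removes the multiplicative batch biases the simulator injects and is
the identity on single-batch data.

States are cut from a hierarchical clustering tree over the SVD-reduced
space (Ward linkage by default); cross-species comparison co-clusters
per-state average profiles on a shared ortholog index with correlation
distance and average linkage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.linalg
from scipy.spatial.distance import pdist

from .core_io import CountMatrix, ProbcellError

logger = logging.getLogger("probcell")


@dataclass
class NormalizedMatrix:
    """log1p-scale expression after depth scaling and batch mean-scaling,
    genes × cells."""

    values: np.ndarray
    gene_ids: list
    cell_ids: list
    batch_factors: pd.DataFrame = None  # genes × batches multiplicative factors

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class ReducedSpace:
    scores: np.ndarray  # cells × d, left-singular basis scaled by singular values
    singular_values: np.ndarray
    d: int
    cell_ids: list
    centering: np.ndarray = None  # per-gene means removed


@dataclass
class StateAssignment:
    labels: dict  # cell_id -> state label
    linkage: np.ndarray  # scipy merge tree with heights
    k: int
    cell_ids: list = field(default_factory=list)

    def label_array(self) -> np.ndarray:
        return np.array([self.labels[c] for c in self.cell_ids])


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

MIN_BATCH_CELLS = 10
FACTOR_CLAMP = (0.1, 10.0)


def normalize_mean_scaling(m: CountMatrix, target_depth: float = None) -> NormalizedMatrix:
    """Depth-scale, log1p-transform and batch-correct by mean scaling.

    Steps: (1) every cell scaled to a common depth (the median library size
    unless ``target_depth`` is given); (2) log1p; (3) per batch and gene,
    values multiplied by pooled-mean / batch-mean computed over cells where
    the gene is detected in that batch, clamped to [0.1, 10]. Batches with
    fewer than 10 cells keep factor 1 with a warning.
    """
    X = m.counts.toarray().astype(float)
    totals = np.maximum(X.sum(axis=0), 1.0)
    depth = float(target_depth) if target_depth else float(np.median(totals))
    V = np.log1p(X / totals[None, :] * depth)

    batches = m.batches()
    batch_names = sorted(set(batches))
    detected = X > 0
    factors = pd.DataFrame(1.0, index=m.gene_ids, columns=batch_names)

    if len(batch_names) > 1:
        # pooled detected-cell mean per gene
        det_total = detected.sum(axis=1)
        pooled = np.divide(
            (V * detected).sum(axis=1), det_total,
            out=np.zeros(m.n_genes), where=det_total > 0,
        )
        for b in batch_names:
            cols = batches == b
            if cols.sum() < MIN_BATCH_CELLS:
                logger.warning("batch too small: %s has %d cells; factor fixed to 1",
                               b, int(cols.sum()))
                continue
            det_b = detected[:, cols]
            n_det = det_b.sum(axis=1)
            batch_mean = np.divide(
                (V[:, cols] * det_b).sum(axis=1), n_det,
                out=np.zeros(m.n_genes), where=n_det > 0,
            )
            f = np.ones(m.n_genes)
            ok = (n_det > 0) & (batch_mean > 0)
            f[ok] = np.clip(pooled[ok] / batch_mean[ok], *FACTOR_CLAMP)
            factors[b] = f
            V[:, cols] *= f[:, None]
    return NormalizedMatrix(values=V, gene_ids=list(m.gene_ids),
                            cell_ids=list(m.barcode_ids), batch_factors=factors)


# ---------------------------------------------------------------------------
# reduction and embedding
# ---------------------------------------------------------------------------


def reduce_svd(nm: NormalizedMatrix, d: int = 30) -> ReducedSpace:
    """Gene-centered truncated SVD; cell scores in the top-d singular basis.

    Signs are fixed deterministically (largest-magnitude loading positive
    per component) so repeated runs are bit-identical.
    """
    if d <= 0:
        raise ProbcellError("invalid rank: d must be positive")
    n_genes, n_cells = nm.values.shape
    if d > min(n_genes, n_cells):
        raise ProbcellError("invalid rank: d exceeds matrix dimensions")
    mu = nm.values.mean(axis=1)
    Xc = nm.values - mu[:, None]
    U, s, Vt = scipy.linalg.svd(Xc, full_matrices=False)
    # deterministic sign convention
    for j in range(min(d, len(s))):
        i = np.argmax(np.abs(U[:, j]))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]
            Vt[j, :] = -Vt[j, :]
    scores = (Vt[:d, :] * s[:d, None]).T  # cells × d
    return ReducedSpace(scores=scores, singular_values=s[:d], d=d,
                        cell_ids=list(nm.cell_ids), centering=mu)


def hcluster_states(rs: ReducedSpace, k: int = 3, linkage: str = "ward") -> StateAssignment:
    """Cut an agglomerative tree over the reduced space into k states."""
    if k < 1:
        raise ProbcellError("k must be >= 1")
    n = rs.scores.shape[0]
    if k > n:
        raise ProbcellError("too many clusters: k exceeds number of cells")
    if linkage not in ("ward", "average"):
        raise ProbcellError(f"unsupported linkage: {linkage}")
    Z = sch.linkage(rs.scores, method=linkage)
    flat = sch.fcluster(Z, t=k, criterion="maxclust")
    labels = {c: f"state{flat[i]}" for i, c in enumerate(rs.cell_ids)}
    return StateAssignment(labels=labels, linkage=Z, k=k, cell_ids=list(rs.cell_ids))


def embed_2d(rs: ReducedSpace, method: str = "svd2", seed: int = 0) -> np.ndarray:
    """2D coordinates for trajectory fitting and display.

    ``svd2`` returns the first two score columns verbatim; ``umap`` runs the
    umap-learn embedding on the reduced scores with a fixed seed.
    """
    if method == "svd2":
        if rs.d < 2:
            raise ProbcellError("need at least 2 components for embedding")
        return rs.scores[:, :2]
    if method == "umap":
        import umap  # deferred: slow import

        reducer = umap.UMAP(n_components=2, random_state=seed)
        return np.asarray(reducer.fit_transform(rs.scores))
    raise ProbcellError(f"invalid method: {method}")


# ---------------------------------------------------------------------------
# state profiles and cross-species co-clustering
# ---------------------------------------------------------------------------


def average_state_profiles(nm: NormalizedMatrix, states: StateAssignment,
                           species_tag: str = "") -> pd.DataFrame:
    """Per-state per-gene mean of normalized values (states × genes).

    Row index is ``species_tag:state`` when a tag is given, so profiles
    from several species can be concatenated on a shared ortholog index.
    """
    cell_pos = {c: i for i, c in enumerate(nm.cell_ids)}
    missing = [c for c in states.labels if c not in cell_pos]
    if missing:
        raise ProbcellError(f"state cells missing from matrix: {missing[:3]}")
    rows = {}
    for state in sorted(set(states.labels.values())):
        cols = [cell_pos[c] for c, s in states.labels.items() if s == state]
        if not cols:
            raise ProbcellError(f"empty state: {state}")
        name = f"{species_tag}:{state}" if species_tag else state
        rows[name] = nm.values[:, cols].mean(axis=1)
    return pd.DataFrame(rows, index=nm.gene_ids).T


def cocluster_profiles(profiles: pd.DataFrame):
    """Hierarchical tree over state profiles: correlation distance, average
    linkage. Returns (linkage matrix, row order)."""
    if profiles.shape[0] < 2:
        raise ProbcellError("need at least two profiles to co-cluster")
    D = pdist(profiles.to_numpy(), metric="correlation")
    Z = sch.linkage(D, method="average")
    return Z, list(profiles.index)


def linkage_to_newick(Z: np.ndarray, leaf_names) -> str:
    """Export a scipy linkage tree as a Newick string."""
    tree = sch.to_tree(Z)

    def rec(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"
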