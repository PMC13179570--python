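"""Principal-curve pseudotime and expression-weighted gene ordering.

A smooth one-dimensional curve is fitted to the 2D embedding by the
projection–smoothing iteration of Hastie & Stuetzle: starting from the
first principal-component line, cells are projected onto the current
polyline to get an arc-length parameter λ, each embedding coordinate is
smoothed as a function of λ with a local-linear (lowess) smoother, and the
curve is re-parameterized by arc length until the mean squared projection
distance stabilizes. λ is min-max scaled to [0, 1] and oriented so that a
designated start marker (e.g. the SELL homolog marking "young"
neutrophils) sits at the low end.

A gene's pseudotime is the average of cell λ values weighted by the gene's
log expression, with an expression-weighted standard deviation; the
resulting ordering feeds preranked gene-set enrichment and cross-species
comparison through an ortholog map.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from statsmodels.nonparametric.smoothers_lowess import lowess

from .core_io import ProbcellError
from .normalize_embed import NormalizedMatrix


@dataclass
class PrincipalCurve:
    curve_points: np.ndarray  # ordered polyline, n_points × 2
    lam: np.ndarray  # per-cell arc-length position scaled to [0, 1]
    cell_ids: list
    oriented: bool = False
    anchor_gene: str = ""
    n_iterations: int = 0
    converged: bool = False


@dataclass
class GenePseudotime:
    gene_id: str
    mean_pt: float  # expression-weighted mean λ; NaN when total_weight == 0
    sd_pt: float
    total_weight: float


# ---------------------------------------------------------------------------
# curve fitting
# ---------------------------------------------------------------------------


def _project_to_polyline(points: np.ndarray, poly: np.ndarray):
    """Project points onto a polyline; returns (arc-length λ, squared distance)."""
    seg = np.diff(poly, axis=0)  # m × 2
    seg_len2 = np.maximum((seg ** 2).sum(axis=1), 1e-300)
    seg_len = np.sqrt(seg_len2)
    arc = np.concatenate([[0.0], np.cumsum(seg_len)])
    best_d2 = np.full(points.shape[0], np.inf)
    best_lam = np.zeros(points.shape[0])
    for i in range(seg.shape[0]):
        rel = points - poly[i]
        t = np.clip(rel @ seg[i] / seg_len2[i], 0.0, 1.0)
        foot = poly[i] + t[:, None] * seg[i]
        d2 = ((points - foot) ** 2).sum(axis=1)
        upd = d2 < best_d2
        best_d2[upd] = d2[upd]
        best_lam[upd] = arc[i] + t[upd] * seg_len[i]
    return best_lam, best_d2


def _smooth_polyline(coords: np.ndarray, lam: np.ndarray, span: float,
                     n_points: int) -> np.ndarray:
    """Smooth each coordinate against λ with lowess and resample the result
    to an n_points polyline on an even λ grid."""
    grid = np.linspace(lam.min(), lam.max(), n_points)
    out = np.empty((n_points, coords.shape[1]))
    order = np.argsort(lam, kind="stable")
    lam_s = lam[order]
    for j in range(coords.shape[1]):
        sm = lowess(coords[order, j], lam_s, frac=span, it=0, return_sorted=True)
        out[:, j] = np.interp(grid, sm[:, 0], sm[:, 1])
    return out


def fit_principal_curve(coords: np.ndarray, cell_ids=None, smoother_span: float = 0.3,
                        max_iter: int = 50, tol: float = 1e-4,
                        n_points: int = 100) -> PrincipalCurve:
    """Hastie–Stuetzle principal curve on 2D embedding coordinates.

    Deterministic: initialization is the first principal-component line and
    the smoother has no stochastic component.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 10:
        raise ProbcellError("need at least 10 cells with 2D coordinates")
    if not np.all(np.isfinite(coords)):
        raise ProbcellError("coordinates must be finite")
    mu = coords.mean(axis=0)
    Xc = coords - mu
    if np.allclose(Xc, 0):
        raise ProbcellError("zero-variance input: all coordinates identical")
    cell_ids = list(cell_ids) if cell_ids is not None else \
        [f"cell{i:05d}" for i in range(coords.shape[0])]

    # initialize with the PC1 line
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    lam = Xc @ Vt[0]
    lo, hi = lam.min(), lam.max()
    poly = mu + np.linspace(lo, hi, n_points)[:, None] * Vt[0]

    lam, d2 = _project_to_polyline(coords, poly)
    prev_msd = float(d2.mean())
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        poly = _smooth_polyline(coords, lam, smoother_span, n_points)
        lam, d2 = _project_to_polyline(coords, poly)
        msd = float(d2.mean())
        if abs(prev_msd - msd) < tol:
            converged = True
            break
        prev_msd = msd

    rng_ = lam.max() - lam.min()
    lam_scaled = (lam - lam.min()) / rng_ if rng_ > 0 else np.zeros_like(lam)
    return PrincipalCurve(curve_points=poly, lam=lam_scaled, cell_ids=cell_ids,
                          n_iterations=n_iter, converged=converged)


def orient_curve(pc: PrincipalCurve, anchor_expression,
                 anchor_gene: str = "") -> PrincipalCurve:
    """Point λ=0 at the start marker: if the anchor's expression-weighted
    mean λ exceeds the unweighted mean λ of all cells — i.e. the marker is
    enriched toward the late end relative to the population (the comparison
    point reduces to 0.5 when cells spread symmetrically along the curve) —
    reverse the curve. Idempotent."""
    w = np.asarray(anchor_expression, dtype=float)
    if w.shape[0] != pc.lam.shape[0]:
        raise ProbcellError("anchor expression length does not match cells")
    if np.all(w == 0):
        raise ProbcellError("uninformative anchor: expression is all zero")
    wmean = float(np.sum(w * pc.lam) / np.sum(w))
    if wmean > float(pc.lam.mean()):
        return replace(pc, lam=1.0 - pc.lam, curve_points=pc.curve_points[::-1].copy(),
                       oriented=True, anchor_gene=anchor_gene)
    return replace(pc, oriented=True, anchor_gene=anchor_gene)


# ---------------------------------------------------------------------------
# expression-weighted gene pseudotime
# ---------------------------------------------------------------------------


def gene_pseudotime(pc: PrincipalCurve, nm: NormalizedMatrix):
    """Per-gene expression-weighted mean and SD of λ.

    Weights are the normalized log1p expression values; a gene with zero
    total weight carries NaN and is excluded from rankings.
    """
    if list(nm.cell_ids) != list(pc.cell_ids):
        pos = {c: i for i, c in enumerate(nm.cell_ids)}
        missing = [c for c in pc.cell_ids if c not in pos]
        if missing:
            raise ProbcellError(f"cells missing from normalized matrix: {missing[:3]}")
        W = nm.values[:, [pos[c] for c in pc.cell_ids]]
    else:
        W = nm.values
    lam = pc.lam
    tw = W.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = (W @ lam) / tw
        # two-pass weighted variance: immune to cancellation, exact at
        # single-support genes
        dev2 = (lam[None, :] - mean[:, None]) ** 2
        var = (W * dev2).sum(axis=1) / tw
    out = []
    for i, g in enumerate(nm.gene_ids):
        if tw[i] > 0:
            out.append(GenePseudotime(g, float(mean[i]),
                                      float(np.sqrt(max(var[i], 0.0))), float(tw[i])))
        else:
            out.append(GenePseudotime(g, float("nan"), float("nan"), 0.0))
    return out


def gps_to_frame(gps) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [g.gene_id for g in gps],
            "mean_pt": [g.mean_pt for g in gps],
            "sd_pt": [g.sd_pt for g in gps],
            "total_weight": [g.total_weight for g in gps],
        }
    ).set_index("gene")


def export_ranking(gps) -> pd.DataFrame:
    """Genes ordered by mean pseudotime, descending, for preranked GSEA
    (.rnk convention). Ties break lexicographically; zero-weight genes are
    omitted."""
    df = gps_to_frame(gps)
    df = df[df["total_weight"] > 0]
    if df.empty:
        raise ProbcellError("nothing to rank: no gene has positive weight")
    df = df.reset_index().sort_values(["mean_pt", "gene"], ascending=[False, True])
    return df[["gene", "mean_pt"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# cross-species comparison
# ---------------------------------------------------------------------------


def crossspecies_correlation(gps_a, gps_b, orthologs: pd.DataFrame) -> dict:
    """Pearson correlation of gene mean pseudotimes across species.

    ``orthologs`` is a two-column map (species A gene, species B gene).
    Only one-to-one pairs are used; many-to-many pairs are dropped and
    counted. Genes measured in only one species are reported separately.
    """
    if orthologs.empty:
        raise ProbcellError("ortholog map is empty")
    omap = orthologs.iloc[:, :2].copy()
    omap.columns = ["gene_a", "gene_b"]
    one_to_one = omap[~omap["gene_a"].duplicated(keep=False)
                      & ~omap["gene_b"].duplicated(keep=False)]
    n_dropped = len(omap) - len(one_to_one)

    fa = gps_to_frame(gps_a)
    fb = gps_to_frame(gps_b)
    merged = (
        one_to_one
        .join(fa["mean_pt"].rename("mean_pt_a"), on="gene_a")
        .join(fb["mean_pt"].rename("mean_pt_b"), on="gene_b")
    )
    both = merged.dropna(subset=["mean_pt_a", "mean_pt_b"])
    only_a = merged["mean_pt_a"].notna() & merged["mean_pt_b"].isna()
    only_b = merged["mean_pt_b"].notna() & merged["mean_pt_a"].isna()
    if len(both) < 2:
        raise ProbcellError("no overlap: fewer than two shared orthologs with pseudotimes")
    r, _ = pearsonr(both["mean_pt_a"], both["mean_pt_b"])
    return {
        "r": float(r),
        "n_shared": int(len(both)),
        "n_only_a": int(only_a.sum()),
        "n_only_b": int(only_b.sum()),
        "n_many_to_many_dropped": int(n_dropped),
        "merged": both.reset_index(drop=True),
    }
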