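"""Probability-based cell typing on raw, unfiltered count matrices.

The classifier performs quality control and cell-type assignment in one
step. Instead of discarding barcodes below a fixed UMI or detected-gene
threshold, it augments an annotated reference with a synthetic **debris**
class — every reference cell is diluted by binomial thinning to 1/factor
of its coverage (factor 20 by default) — and fits an L2-penalized
multinomial logistic regression over all real types plus debris. A new
barcode is then assigned by competing probabilities: genuinely shallow cell
types (tumor-associated neutrophils often show <500 detected genes) win
against the debris class when their type-specific program is present, while
ambient-soup barcodes do not.

Features are log1p **raw** panel counts plus (by default) log1p total UMI.
Depth is deliberately not normalized away: the debris class is defined by
low coverage, so depth carries the competing-class signal.

The penalized likelihood, its gradient and the L-BFGS fit are implemented
here; nothing about the model is delegated to a fitted library estimator.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.sparse as sp
from scipy.special import logsumexp
from scipy.stats import gaussian_kde

from .core_io import DEBRIS_LABEL, UNASSIGNED_LABEL, CountMatrix, ProbcellError, validate_annotations

logger = logging.getLogger("probcell")


# ---------------------------------------------------------------------------
# training-set construction: panel, thinning, debris augmentation
# ---------------------------------------------------------------------------


@dataclass
class DebrisFactor:
    """Coverage dilution factor for the synthetic debris class (default 20:
    reference profiles are resampled to 20 times less coverage)."""

    factor: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if self.factor <= 1:
            raise ProbcellError("invalid factor: debris dilution factor must be > 1")


@dataclass
class TrainingSet:
    features: np.ndarray  # (cells + debris) × (panel genes [+ depth])
    labels: np.ndarray  # per-row class, includes "debris"
    panel: list  # ordered gene ids
    depth_feature_included: bool = True


@dataclass
class ClassifierModel:
    """Multinomial logistic coefficients over a gene panel; debris is the
    last class by convention."""

    classes: list
    coefficients: np.ndarray  # classes × features
    intercepts: np.ndarray  # per class
    panel: list
    depth_feature_included: bool = True
    regularization: dict = field(default_factory=lambda: {"type": "L2", "strength": 1.0})
    training_meta: dict = field(default_factory=dict)


@dataclass
class ClassificationResult:
    barcode_id: str
    probabilities: np.ndarray  # over model.classes, sums to 1
    called_label: str
    max_prob: float


@dataclass
class AdtThreshold:
    """Present/absent cutoff for an antibody-capture channel, placed at the
    density trough between the two modes of log1p raw counts."""

    threshold: float
    modes: tuple
    valid: bool
    reason: str = ""


def select_panel(ref: CountMatrix, panel_size: int) -> list:
    """The ``panel_size`` most variable genes of log1p CPM expression."""
    if panel_size > ref.n_genes:
        raise ProbcellError("panel_size exceeds number of genes")
    totals = np.maximum(ref.total_counts(), 1)
    X = ref.counts.toarray().astype(float)
    cpm = np.log1p(X / totals[None, :] * 1e6)
    var = cpm.var(axis=1)
    # stable order among ties: higher variance first, then gene index
    order = np.lexsort((np.arange(ref.n_genes), -var))
    return [ref.gene_ids[i] for i in order[:panel_size]]


def thin_counts(counts, factor: float, rng) -> np.ndarray:
    """Binomial thinning: each count keeps Binomial(count, 1/factor) reads,
    so E[thinned] = count / factor per gene."""
    arr = np.asarray(counts.toarray() if sp.issparse(counts) else counts)
    return rng.binomial(arr.astype(np.int64), 1.0 / factor)


def _features_from_counts(panel_counts: np.ndarray, depth_feature: bool,
                          totals=None) -> np.ndarray:
    """log1p raw panel counts, optionally appended with log1p total UMI.
    ``totals`` are full-matrix totals; they default to panel totals."""
    X = np.log1p(panel_counts.astype(float))
    if depth_feature:
        t = panel_counts.sum(axis=1) if totals is None else np.asarray(totals, dtype=float)
        X = np.column_stack([X, np.log1p(t)])
    return X


def make_debris_training(ref: CountMatrix, annotations, d: DebrisFactor = None,
                         panel_size: int = 1000, depth_feature: bool = True) -> TrainingSet:
    """Build the debris-augmented training set.

    For each annotated cell one debris row is created by thinning every
    count with retention probability 1/factor (1:1 augmentation). Features
    are log1p raw panel counts of the original and thinned profiles.
    """
    d = d or DebrisFactor()
    if not annotations:
        raise ProbcellError("empty reference: no annotations")
    validate_annotations(annotations, ref)
    panel = select_panel(ref, min(panel_size, ref.n_genes))
    gene_index = {g: i for i, g in enumerate(ref.gene_ids)}
    panel_rows = [gene_index[g] for g in panel]

    col_index = {b: i for i, b in enumerate(ref.barcode_ids)}
    cols = [col_index[a.barcode_id] for a in annotations]
    full = ref.counts[:, cols].toarray().T  # cells × genes, annotation order
    rng = np.random.default_rng(d.seed)
    thinned = rng.binomial(full.astype(np.int64), 1.0 / d.factor)

    feats = np.vstack([
        _features_from_counts(full[:, panel_rows], depth_feature, totals=full.sum(axis=1)),
        _features_from_counts(thinned[:, panel_rows], depth_feature, totals=thinned.sum(axis=1)),
    ])
    labels = np.array([a.cell_type for a in annotations] + [DEBRIS_LABEL] * len(annotations))
    return TrainingSet(features=feats, labels=labels, panel=panel,
                       depth_feature_included=depth_feature)


# ---------------------------------------------------------------------------
# penalized multinomial logistic regression
# ---------------------------------------------------------------------------


def multinomial_objective(theta: np.ndarray, X: np.ndarray, Y: np.ndarray,
                          lam: float):
    """Penalized negative log-likelihood and its analytic gradient.

    ``theta`` packs the K×p coefficient matrix followed by K intercepts;
    ``Y`` is the n×K one-hot label matrix. The objective is
    −Σ_i log softmax(XWᵀ + b)_{y_i} + (λ/2)‖W‖², intercepts unpenalized.
    """
    n, p = X.shape
    K = Y.shape[1]
    W = theta[: K * p].reshape(K, p)
    b = theta[K * p:]
    S = X @ W.T + b  # n × K scores
    lse = logsumexp(S, axis=1)
    nll = float(np.sum(lse) - np.sum(S * Y))
    f = nll + 0.5 * lam * float(np.sum(W * W))
    P = np.exp(S - lse[:, None])
    R = P - Y
    gW = R.T @ X + lam * W
    gb = R.sum(axis=0)
    return f, np.concatenate([gW.ravel(), gb])


def train_classifier(ts: TrainingSet, lambda_reg: float = 1.0, seed: int = 0,
                     gtol: float = 1e-6, max_iter: int = 2000) -> ClassifierModel:
    """Fit the L2-penalized multinomial model by L-BFGS from a zero start.

    Deterministic given the training set and strength: the objective is
    convex and the initialization is fixed, so the seed only tags metadata.
    """
    X = np.asarray(ts.features, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ProbcellError("invalid feature: non-finite values in training features")
    classes = sorted(set(ts.labels) - {DEBRIS_LABEL}) + [DEBRIS_LABEL]
    if DEBRIS_LABEL not in ts.labels:
        raise ProbcellError("degenerate class: training set lacks debris rows")
    if len(classes) < 2:
        raise ProbcellError("degenerate class: need at least two classes")
    counts = pd.Series(ts.labels).value_counts()
    empty = [c for c in classes if counts.get(c, 0) == 0]
    if empty:
        raise ProbcellError(f"degenerate class: no rows for {empty}")
    if X.shape[0] < len(classes):
        raise ProbcellError("degenerate class: fewer rows than classes")

    Y = np.zeros((X.shape[0], len(classes)))
    cls_index = {c: k for k, c in enumerate(classes)}
    for i, lab in enumerate(ts.labels):
        Y[i, cls_index[lab]] = 1.0

    K, p = len(classes), X.shape[1]
    n = X.shape[0]

    def scaled(theta):
        # per-row mean of the penalized objective: same argmin, and the
        # gradient tolerance is then independent of the training-set size
        f, g = multinomial_objective(theta, X, Y, lambda_reg)
        return f / n, g / n

    res = scipy.optimize.minimize(
        scaled,
        np.zeros(K * p + K),
        jac=True,
        method="L-BFGS-B",
        options={"gtol": gtol, "ftol": 1e-14, "maxiter": max_iter, "maxcor": 20},
    )
    W = res.x[: K * p].reshape(K, p)
    b = res.x[K * p:]
    return ClassifierModel(
        classes=classes,
        coefficients=W,
        intercepts=b,
        panel=list(ts.panel),
        depth_feature_included=ts.depth_feature_included,
        regularization={"type": "L2", "strength": lambda_reg},
        training_meta={"seed": seed, "n_rows": int(X.shape[0]),
                       "converged": bool(res.success), "n_iter": int(res.nit)},
    )


def select_regularization(ts: TrainingSet, grid=None, folds: int = 5,
                          seed: int = 0) -> float:
    """Pick the L2 strength minimizing cross-validated log-loss over the
    default grid 10^-4 … 10^2."""
    grid = list(grid) if grid is not None else [10.0 ** e for e in range(-4, 3)]
    rng = np.random.default_rng(seed)
    n = ts.features.shape[0]
    fold_of = rng.permutation(np.arange(n) % folds)
    best_lam, best_loss = grid[0], np.inf
    for lam in grid:
        losses = []
        for f in range(folds):
            tr, va = fold_of != f, fold_of == f
            sub = TrainingSet(ts.features[tr], ts.labels[tr], ts.panel,
                              ts.depth_feature_included)
            model = train_classifier(sub, lambda_reg=lam)
            P = _softmax_scores(model, ts.features[va])
            idx = {c: k for k, c in enumerate(model.classes)}
            rows = np.arange(va.sum())
            cols = np.array([idx[c] for c in ts.labels[va]])
            losses.append(-np.mean(np.log(np.maximum(P[rows, cols], 1e-300))))
        loss = float(np.mean(losses))
        if loss < best_loss:
            best_lam, best_loss = lam, loss
    return best_lam


# ---------------------------------------------------------------------------
# prediction and calling
# ---------------------------------------------------------------------------


def _softmax_scores(model: ClassifierModel, X: np.ndarray) -> np.ndarray:
    S = X @ model.coefficients.T + model.intercepts
    return np.exp(S - logsumexp(S, axis=1)[:, None])


def predict_proba(model: ClassifierModel, raw: CountMatrix):
    """Class probabilities for every barcode of a raw, unfiltered matrix.

    No UMI or detected-gene filtering is applied first. Panel genes absent
    from ``raw`` are zero-filled with a warning; more than 50% missing
    aborts rather than emit silently wrong probabilities.
    """
    gene_index = {g: i for i, g in enumerate(raw.gene_ids)}
    present = [g for g in model.panel if g in gene_index]
    missing_frac = 1.0 - len(present) / len(model.panel)
    if missing_frac > 0.5:
        raise ProbcellError(
            f"panel mismatch: {missing_frac:.0%} of panel genes missing from input"
        )
    if missing_frac > 0:
        logger.warning("zero-filling %.1f%% of panel genes absent from input",
                       100 * missing_frac)
    panel_counts = np.zeros((raw.n_barcodes, len(model.panel)))
    rows = [gene_index[g] for g in present]
    sub = raw.counts[rows, :].toarray().T  # barcodes × present panel genes
    present_pos = [j for j, g in enumerate(model.panel) if g in gene_index]
    panel_counts[:, present_pos] = sub
    X = _features_from_counts(panel_counts, model.depth_feature_included,
                              totals=raw.total_counts())
    P = _softmax_scores(model, X)
    k = np.argmax(P, axis=1)
    return [
        ClassificationResult(
            barcode_id=bc,
            probabilities=P[i],
            called_label=model.classes[k[i]],
            max_prob=float(P[i, k[i]]),
        )
        for i, bc in enumerate(raw.barcode_ids)
    ]


def call_cells(results, min_prob: float = 0.5) -> pd.DataFrame:
    """Final labels: argmax class if its probability clears ``min_prob``,
    else ``unassigned``. Ties go to the first class in model order (argmax
    already returns the lowest index on exact ties)."""
    if not 0 <= min_prob <= 1:
        raise ProbcellError("min_prob must be in [0, 1]")
    rows = []
    for r in results:
        label = r.called_label if r.max_prob >= min_prob else UNASSIGNED_LABEL
        rows.append((r.barcode_id, label, r.max_prob))
    return pd.DataFrame(rows, columns=["barcode", "called_label", "max_prob"])


def accepted_cells(calls: pd.DataFrame) -> pd.DataFrame:
    """Calls minus debris and unassigned barcodes (the downstream cell table)."""
    return calls[~calls["called_label"].isin([DEBRIS_LABEL, UNASSIGNED_LABEL])]


def recovery_report(calls: pd.DataFrame, raw: CountMatrix, gene_cutoff: int = 500,
                    expected_types=None) -> pd.DataFrame:
    """Per-type recovery relative to a fixed detected-gene QC cutoff.

    ``fold_vs_cutoff`` = called cells of the type / called cells of the type
    with ≥ cutoff detected genes: how many more cells probability calling
    keeps than the fixed threshold would. The ratio is +inf when no called
    cell clears the cutoff, and NaN (not applicable) for an expected type
    with no called cells at all.
    """
    if gene_cutoff < 0:
        raise ProbcellError("invalid cutoff: gene_cutoff must be >= 0")
    detected = dict(zip(raw.barcode_ids, raw.detected_genes()))
    unknown = set(calls["barcode"]) - set(raw.barcode_ids)
    if unknown:
        raise ProbcellError(f"calls refer to unknown barcodes: {sorted(unknown)[:3]}")
    acc = accepted_cells(calls)
    rows = []
    for cell_type, grp in acc.groupby("called_label"):
        det = np.array([detected[b] for b in grp["barcode"]])
        n = len(grp)
        n_below = int(np.sum(det < gene_cutoff))
        n_above = n - n_below
        fold = n / n_above if n_above > 0 else np.inf
        rows.append((cell_type, n, n_below, fold))
    for cell_type in expected_types or []:
        if cell_type not in {r[0] for r in rows}:
            rows.append((cell_type, 0, 0, np.nan))
    return pd.DataFrame(rows, columns=["cell_type", "n_cells", "n_below_cutoff",
                                       "fold_vs_cutoff"]).set_index("cell_type")


# ---------------------------------------------------------------------------
# antibody-capture (ADT) thresholding
# ---------------------------------------------------------------------------


MIN_TROUGH_DEPTH = 0.2  # the dip must reach 20% below the smaller mode


def adt_threshold(adt_counts, bandwidth=None, grid_size: int = 512) -> AdtThreshold:
    """Present/absent cutoff at the bimodality trough of log1p raw counts.

    A Gaussian kernel density (Silverman bandwidth unless overridden) is the
    smooth analogue of the histogram; the threshold is the density minimum
    between the two highest local maxima. The trough must dip at least 20%
    below the smaller of the two modes, otherwise the sample is treated as
    unimodal (count discreteness produces shallow spurious maxima).
    """
    x = np.log1p(np.asarray(adt_counts, dtype=float))
    if x.size < 50:
        raise ProbcellError("need at least 50 observations for ADT thresholding")
    if np.ptp(x) == 0:
        return AdtThreshold(np.nan, (np.nan, np.nan), False, reason="degenerate")
    kde = gaussian_kde(x, bw_method=bandwidth if bandwidth is not None else "silverman")
    grid = np.linspace(x.min(), x.max(), grid_size)
    dens = kde(grid)
    interior = np.arange(1, grid_size - 1)
    peaks = interior[(dens[interior] > dens[interior - 1]) & (dens[interior] >= dens[interior + 1])]
    if len(peaks) < 2:
        return AdtThreshold(np.nan, (np.nan, np.nan), False, reason="unimodal")
    top2 = peaks[np.argsort(dens[peaks])[-2:]]
    lo, hi = int(top2.min()), int(top2.max())
    trough = lo + int(np.argmin(dens[lo:hi + 1]))
    if dens[trough] > (1.0 - MIN_TROUGH_DEPTH) * min(dens[lo], dens[hi]):
        return AdtThreshold(np.nan, (np.nan, np.nan), False, reason="unimodal")
    return AdtThreshold(
        threshold=float(grid[trough]),
        modes=(float(grid[lo]), float(grid[hi])),
        valid=True,
    )


# ---------------------------------------------------------------------------
# model serialization
# ---------------------------------------------------------------------------

_MODEL_FORMAT_VERSION = 1


def save_model(model: ClassifierModel, path: str) -> str:
    """Serialize the classifier as a self-describing JSON archive."""
    with open(path, "w") as fh:
        json.dump(
            {
                "format_version": _MODEL_FORMAT_VERSION,
                "classes": model.classes,
                "coefficients": model.coefficients.tolist(),
                "intercepts": model.intercepts.tolist(),
                "panel": model.panel,
                "depth_feature_included": model.depth_feature_included,
                "regularization": model.regularization,
                "training_meta": model.training_meta,
            },
            fh,
        )
    return path


def load_model(path: str) -> ClassifierModel:
    with open(path) as fh:
        d = json.load(fh)
    if d.get("format_version") != _MODEL_FORMAT_VERSION:
        raise ProbcellError("unsupported model format version")
    return ClassifierModel(
        classes=d["classes"],
        coefficients=np.array(d["coefficients"]),
        intercepts=np.array(d["intercepts"]),
        panel=d["panel"],
        depth_feature_included=d["depth_feature_included"],
        regularization=d["regularization"],
        training_meta=d["training_meta"],
    )
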