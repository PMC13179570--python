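"""Pseudobulk-trained penalized prediction of neutrophil abundance in bulk.

Training samples are pseudobulk profiles — per-sample means of normalized
single-cell expression — labelled with the neutrophil fraction among the
classifier-accepted cells of that sample. An elastic-net-penalized least
squares model (glmnet-style: mixing parameter ``alpha``, regularization
path ``lambda``) maps standardized expression features to the fraction;
the path point is chosen by minimum cross-validated MSE. Applied to bulk
expression on the same feature scale, the scores are relative abundances
used for ranking and hi/lo stratification, not calibrated fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold

from .core_io import ProbcellError
from .classify import accepted_cells
from .normalize_embed import NormalizedMatrix

logger = logging.getLogger("probcell")


@dataclass
class PseudobulkProfile:
    sample_id: str
    features: pd.Series  # per-gene mean normalized expression
    neutrophil_fraction: float

    def __post_init__(self):
        if not 0 <= self.neutrophil_fraction <= 1:
            raise ProbcellError("neutrophil_fraction must be in [0, 1]")
        if not np.all(np.isfinite(self.features.to_numpy(dtype=float))):
            raise ProbcellError("pseudobulk features must be finite")


@dataclass
class AbundanceModel:
    coefficients: pd.Series  # per-gene weights on standardized features
    intercept: float
    feature_genes: list
    transform: str = "identity"  # applied to bulk input: "identity" | "log1p"
    feature_means: np.ndarray = None  # standardization offsets (None = none)
    feature_scales: np.ndarray = None
    penalty: dict = field(default_factory=dict)  # alpha, lambda_path, lambda_selected
    cv: dict = field(default_factory=dict)


@dataclass
class SampleStratification:
    groups: pd.Series  # sample_id -> group label
    thresholds: dict


# ---------------------------------------------------------------------------
# pseudobulk construction
# ---------------------------------------------------------------------------


def build_pseudobulk(nm: NormalizedMatrix, calls: pd.DataFrame, sample_of: dict,
                     target_label: str = "neutrophil"):
    """Per-sample mean expression plus the fraction of accepted cells called
    ``target_label``. Samples named in ``sample_of`` with no accepted cell
    raise ``empty sample``."""
    acc = accepted_cells(calls)
    missing = [b for b in acc["barcode"] if b not in sample_of]
    if missing:
        raise ProbcellError(f"called cells lack sample labels: {missing[:3]}")
    cell_pos = {c: i for i, c in enumerate(nm.cell_ids)}
    by_sample = {}
    for b, label in zip(acc["barcode"], acc["called_label"]):
        by_sample.setdefault(sample_of[b], []).append((b, label))
    empty = set(sample_of.values()) - set(by_sample)
    if empty:
        raise ProbcellError(f"empty sample: no accepted cells in {sorted(empty)[:3]}")
    profiles = []
    for sample in sorted(by_sample):
        cells = by_sample[sample]
        cols = [cell_pos[b] for b, _ in cells]
        feats = pd.Series(nm.values[:, cols].mean(axis=1), index=nm.gene_ids)
        frac = sum(1 for _, lab in cells if lab == target_label) / len(cells)
        profiles.append(PseudobulkProfile(sample, feats, frac))
    return profiles


# ---------------------------------------------------------------------------
# model fitting and prediction
# ---------------------------------------------------------------------------


def train_abundance_model(profiles, alpha: float = 0.5, folds: int = 5,
                          seed: int = 0, n_lambdas: int = 100) -> AbundanceModel:
    """Elastic-net fit of neutrophil fraction on standardized features with
    the path point chosen by minimum cross-validated MSE."""
    if folds < 2:
        raise ProbcellError("invalid folds: need at least 2")
    if len(profiles) < 2 * folds:
        raise ProbcellError("need at least 2*folds training profiles")
    genes = list(profiles[0].features.index)
    X = np.array([p.features.reindex(genes).to_numpy(dtype=float) for p in profiles])
    y = np.array([p.neutrophil_fraction for p in profiles])
    if np.allclose(y, y[0]):
        raise ProbcellError("degenerate outcome: fractions are all identical")

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd

    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    enet = ElasticNetCV(l1_ratio=alpha, alphas=n_lambdas, cv=cv,
                        max_iter=20000, tol=1e-6, random_state=seed)
    enet.fit(Xs, y)
    mse_cv = enet.mse_path_.mean(axis=-1).min()
    cv_r2 = 1.0 - mse_cv / y.var() if y.var() > 0 else 0.0
    return AbundanceModel(
        coefficients=pd.Series(enet.coef_, index=genes),
        intercept=float(enet.intercept_),
        feature_genes=genes,
        transform="identity",
        feature_means=mu,
        feature_scales=sd,
        penalty={"alpha": alpha, "lambda_path": enet.alphas_.tolist(),
                 "lambda_selected": float(enet.alpha_)},
        cv={"folds": folds, "seed": seed, "criterion": "mse", "cv_r2": float(cv_r2)},
    )


def predict_abundance(model: AbundanceModel, bulk: pd.DataFrame) -> pd.Series:
    """Relative abundance score per bulk sample (rows = samples).

    The model's transform tag is applied, model genes absent from the bulk
    matrix are zero-filled with a warning (>50% missing aborts) and the
    standardized dot product plus intercept is returned, unclipped.
    """
    vals = bulk.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ProbcellError("invalid bulk value: non-finite entries")
    present = [g for g in model.feature_genes if g in bulk.columns]
    missing_frac = 1.0 - len(present) / len(model.feature_genes)
    if missing_frac > 0.5:
        raise ProbcellError(f"feature mismatch: {missing_frac:.0%} of model genes missing")
    if missing_frac > 0:
        logger.warning("zero-filling %.1f%% of model genes absent from bulk",
                       100 * missing_frac)
    X = bulk.reindex(columns=model.feature_genes, fill_value=0.0).to_numpy(dtype=float)
    if model.transform == "log1p":
        X = np.log1p(X)
    elif model.transform != "identity":
        raise ProbcellError(f"unknown transform: {model.transform}")
    if model.feature_means is not None:
        X = (X - model.feature_means) / model.feature_scales
    scores = X @ model.coefficients.to_numpy() + model.intercept
    return pd.Series(scores, index=bulk.index, name="abundance_score")


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------


def stratify_samples(scores: pd.Series, second_variable: pd.Series = None,
                     thresholds: dict = None) -> SampleStratification:
    """hi/lo split at the median (ties to "lo"); a second variable crosses
    the split into four groups."""
    if len(scores) < 2:
        raise ProbcellError("need at least 2 samples to stratify")
    thresholds = dict(thresholds or {})
    t1 = thresholds.get("primary", float(np.median(scores)))
    primary = np.where(scores > t1, "hi", "lo")
    used = {"primary": t1}
    if second_variable is not None:
        sv = second_variable.reindex(scores.index)
        if sv.isna().any():
            raise ProbcellError("second variable missing for some samples")
        t2 = thresholds.get("second", float(np.median(sv)))
        second = np.where(sv > t2, "hi", "lo")
        labels = [f"{a}_{b}" for a, b in zip(primary, second)]
        used["second"] = t2
    else:
        labels = list(primary)
    return SampleStratification(
        groups=pd.Series(labels, index=scores.index, name="group"),
        thresholds=used,
    )
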