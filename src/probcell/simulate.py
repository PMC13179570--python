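"""Synthetic data generators with the statistical structure the pipeline assumes.

Three regimes are produced, each a pure function of (config, seed):

* **reference / mixture** — several cell types with type-specific expression
  programs sampled multinomially at negative-binomial library sizes. One
  type is deliberately shallow (neutrophil-like, mean library ~400, median
  detected genes below the conventional 500-gene QC cutoff) while the other
  types are deep (>1000 detected genes), reproducing the regime in which
  fixed thresholds discard real cells.
* **debris** — ambient-soup barcodes drawn from the library-size-weighted
  mixture of all type programs at very low totals. Soup-shaped debris is the
  hard competing class: uniform noise would be trivially separable.
* **trajectory / bulk** — a latent differentiation time in [0,1] driving
  monotone gene programs, and bulk cohorts mixed from component profiles
  with known fractions under multiplicative log-normal noise.

Batch effects are per-gene multiplicative biases applied to the program
weights *before* sampling, matching the multiplicative mean-scaling
correction model downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_io import CellAnnotation, CountMatrix, ProbcellError

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class CellTypeSpec:
    """One cell type: its size, depth distribution and expression program."""

    name: str
    n_cells: int
    mean_library_size: float
    library_size_dispersion: float  # NB size parameter; larger = less dispersed
    program: np.ndarray  # per-gene relative expression, sums to 1

    def __post_init__(self):
        self.program = np.asarray(self.program, dtype=float)
        if np.any(self.program < 0):
            raise ProbcellError("program weights must be non-negative")
        s = self.program.sum()
        if not np.isclose(s, 1.0):
            if s <= 0:
                raise ProbcellError("program weights must have positive sum")
            self.program = self.program / s
        if self.mean_library_size <= 0:
            raise ProbcellError("mean_library_size must be > 0")
        if self.n_cells < 0:
            raise ProbcellError("n_cells must be >= 0")


@dataclass
class BatchSpec:
    name: str
    bias_scale: float = 0.0  # sd of per-gene log-normal multiplicative bias


@dataclass
class SimulationConfig:
    n_genes: int
    cell_types: list
    n_debris: int = 0
    debris_library_range: tuple = (20, 400)
    batches: list = field(default_factory=lambda: [BatchSpec("batch0", 0.0)])
    seed: int = 0


@dataclass
class TrajectoryConfig:
    n_cells: int
    n_genes: int
    monotone_up_genes: list = field(default_factory=list)
    monotone_down_genes: list = field(default_factory=list)
    effect_size: float = 2.0  # log2-fold range across the full time axis
    mean_library_size: float = 2000.0
    library_size_dispersion: float = 10.0
    seed: int = 0

    def __post_init__(self):
        up, down = set(self.monotone_up_genes), set(self.monotone_down_genes)
        if up & down:
            raise ProbcellError("index collision: a gene cannot be both monotone up and down")
        if self.effect_size < 0:
            raise ProbcellError("effect_size must be >= 0")


@dataclass
class BulkCohortConfig:
    n_samples: int
    component_profiles: dict  # type name -> per-gene linear expression vector
    concentrations: dict  # type name -> Dirichlet concentration
    measurement_noise_sd: float = 0.1  # on the log scale
    seed: int = 0


# ---------------------------------------------------------------------------
# programs and defaults
# ---------------------------------------------------------------------------


def make_programs(n_genes: int, type_names, seed: int = 0,
                  markers_per_type: int = 60, marker_boost: float = 25.0) -> dict:
    """Type-specific expression programs over a shared gene index.

    Each program is a log-normal baseline over all genes with a disjoint
    block of marker genes boosted, so types share a broad background (as
    real transcriptomes do) but remain identifiable.
    """
    rng = np.random.default_rng(seed)
    programs = {}
    for i, name in enumerate(type_names):
        w = np.exp(rng.normal(0.0, 1.0, size=n_genes))
        lo = i * markers_per_type
        hi = min(lo + markers_per_type, n_genes)
        w[lo:hi] *= marker_boost
        programs[name] = w / w.sum()
    return programs


#: names used by the default reference regime; the first is the shallow type
DEFAULT_TYPE_NAMES = ("neutrophil", "t_cell", "b_cell", "macrophage", "epithelial")


def default_reference_config(seed: int = 0, n_cells_per_type: int = 500,
                             n_genes: int = 2000, n_debris: int = 0,
                             batches=None, program_seed: int = 0) -> SimulationConfig:
    """The default five-type regime: one shallow neutrophil-like type
    (mean library 400, median detected genes < 500) among four deep types.

    ``program_seed`` fixes the type programs (the biology) independently of
    ``seed`` (the sampling noise), so datasets at different seeds share the
    same type signatures, as a reference and a query cohort would.
    """
    programs = make_programs(n_genes, DEFAULT_TYPE_NAMES, seed=program_seed)
    depth = {"neutrophil": (400.0, 8.0)}
    types = [
        CellTypeSpec(
            name=name,
            n_cells=n_cells_per_type,
            mean_library_size=depth.get(name, (5000.0, 8.0))[0],
            library_size_dispersion=depth.get(name, (5000.0, 8.0))[1],
            program=programs[name],
        )
        for name in DEFAULT_TYPE_NAMES
    ]
    return SimulationConfig(
        n_genes=n_genes,
        cell_types=types,
        n_debris=n_debris,
        debris_library_range=(20, 300),
        batches=batches or [BatchSpec("batch0", 0.0)],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def _nb_library_sizes(rng, n, mean, dispersion):
    """Negative-binomial totals via the Gamma-Poisson mixture, floored at 1."""
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion, size=n)
    return np.maximum(rng.poisson(lam), 1)


def _batch_biases(cfg: SimulationConfig, rng) -> dict:
    return {
        b.name: np.exp(rng.normal(0.0, b.bias_scale, size=cfg.n_genes))
        if b.bias_scale > 0
        else np.ones(cfg.n_genes)
        for b in cfg.batches
    }


def simulate_reference(cfg: SimulationConfig, barcode_prefix: str = "cell"):
    """Sample an annotated multi-type count matrix.

    Returns ``(CountMatrix, list[CellAnnotation])``. Per cell: the library
    size is negative-binomial for its type, the batch's per-gene bias is
    multiplied into the type program (renormalized) and counts are drawn
    multinomially.
    """
    if not cfg.cell_types:
        raise ProbcellError("no types: cell_types is empty")
    rng = np.random.default_rng(cfg.seed)
    biases = _batch_biases(cfg, rng)
    batch_names = [b.name for b in cfg.batches]

    cols, barcodes, annotations, batch_of = [], [], [], {}
    i = 0
    for spec in cfg.cell_types:
        sizes = _nb_library_sizes(rng, spec.n_cells, spec.mean_library_size,
                                  spec.library_size_dispersion)
        for j in range(spec.n_cells):
            batch = batch_names[i % len(batch_names)]
            p = spec.program * biases[batch]
            p = p / p.sum()
            cols.append(rng.multinomial(sizes[j], p))
            bc = f"{barcode_prefix}{i:05d}"
            barcodes.append(bc)
            batch_of[bc] = batch
            annotations.append(CellAnnotation(bc, spec.name, source="simulated"))
            i += 1
    counts = sp.csc_matrix(np.array(cols, dtype=np.int64).T) if cols else \
        sp.csc_matrix((cfg.n_genes, 0), dtype=np.int64)
    m = CountMatrix(
        gene_ids=[f"gene{g:04d}" for g in range(cfg.n_genes)],
        barcode_ids=barcodes,
        counts=counts,
        batch_of=batch_of,
    )
    return m, annotations


def ambient_soup(cfg: SimulationConfig) -> np.ndarray:
    """Library-size-weighted mixture of the type programs (the expected
    composition of free-floating transcripts)."""
    w = np.zeros(cfg.n_genes)
    for spec in cfg.cell_types:
        w += spec.n_cells * spec.mean_library_size * spec.program
    return w / w.sum()


def simulate_debris(cfg: SimulationConfig, barcode_prefix: str = "debris"):
    """Sample ambient-soup barcodes with totals uniform in the debris range."""
    lo, hi = cfg.debris_library_range
    if lo > hi:
        raise ProbcellError("invalid range: debris_library_range min > max")
    if cfg.n_debris < 0:
        raise ProbcellError("n_debris must be >= 0")
    rng = np.random.default_rng(cfg.seed + 1)
    gene_ids = [f"gene{g:04d}" for g in range(cfg.n_genes)]
    if cfg.n_debris == 0:
        return CountMatrix(gene_ids=gene_ids, barcode_ids=[],
                           counts=sp.csc_matrix((cfg.n_genes, 0), dtype=np.int64))
    soup = ambient_soup(cfg)
    totals = rng.integers(lo, hi + 1, size=cfg.n_debris)
    cols = [rng.multinomial(t, soup) for t in totals]
    batch_names = [b.name for b in cfg.batches]
    barcodes = [f"{barcode_prefix}{i:05d}" for i in range(cfg.n_debris)]
    return CountMatrix(
        gene_ids=gene_ids,
        barcode_ids=barcodes,
        counts=sp.csc_matrix(np.array(cols, dtype=np.int64).T),
        batch_of={bc: batch_names[i % len(batch_names)] for i, bc in enumerate(barcodes)},
    )


def combine_matrices(a: CountMatrix, b: CountMatrix) -> CountMatrix:
    """Column-concatenate two matrices sharing a gene index."""
    if a.gene_ids != b.gene_ids:
        raise ProbcellError("gene index mismatch")
    return CountMatrix(
        gene_ids=list(a.gene_ids),
        barcode_ids=a.barcode_ids + b.barcode_ids,
        counts=sp.hstack([a.counts, b.counts]).tocsc(),
        batch_of={**a.batch_of, **b.batch_of},
        sample_of={**a.sample_of, **b.sample_of},
    )


def trajectory_expected_weights(cfg: TrajectoryConfig, base: np.ndarray,
                                t: np.ndarray) -> np.ndarray:
    """Expected per-gene sampling weights at latent times ``t`` (cells × genes,
    rows normalized). Monotone-up genes gain ``effect_size`` log2-fold across
    the time axis; monotone-down genes lose it; the rest are flat."""
    logfc = np.zeros(cfg.n_genes)
    logfc[list(cfg.monotone_up_genes)] = cfg.effect_size
    logfc[list(cfg.monotone_down_genes)] = -cfg.effect_size
    w = base[None, :] * np.exp2(np.outer(t - 0.5, logfc))
    return w / w.sum(axis=1, keepdims=True)


def simulate_trajectory(cfg: TrajectoryConfig):
    """Sample a count matrix driven by a latent differentiation time.

    Returns ``(CountMatrix, latent_time)`` with latent times uniform on
    [0, 1] as ground truth.
    """
    rng = np.random.default_rng(cfg.seed)
    t = rng.uniform(0.0, 1.0, size=cfg.n_cells)
    base = np.exp(rng.normal(0.0, 0.5, size=cfg.n_genes))
    weights = trajectory_expected_weights(cfg, base, t)
    sizes = _nb_library_sizes(rng, cfg.n_cells, cfg.mean_library_size,
                              cfg.library_size_dispersion)
    cols = [rng.multinomial(sizes[i], weights[i]) for i in range(cfg.n_cells)]
    m = CountMatrix(
        gene_ids=[f"gene{g:04d}" for g in range(cfg.n_genes)],
        barcode_ids=[f"cell{i:05d}" for i in range(cfg.n_cells)],
        counts=sp.csc_matrix(np.array(cols, dtype=np.int64).T)
        if cols else sp.csc_matrix((cfg.n_genes, 0), dtype=np.int64),
    )
    return m, t


def simulate_bulk(cfg: BulkCohortConfig):
    """Sample bulk samples as known mixtures of component profiles.

    Returns ``(bulk, fractions)`` as DataFrames: ``bulk`` is samples × genes
    with expectation Σ_t fraction_t · profile_t under multiplicative
    log-normal noise; ``fractions`` carries the ground truth per sample.
    """
    names = list(cfg.component_profiles)
    if not names:
        raise ProbcellError("no component profiles")
    profiles = [np.asarray(cfg.component_profiles[n], dtype=float) for n in names]
    n_genes = profiles[0].size
    if any(p.size != n_genes for p in profiles):
        raise ProbcellError("gene index mismatch: component profiles differ in length")
    P = np.array(profiles)  # types × genes
    rng = np.random.default_rng(cfg.seed)
    conc = np.array([cfg.concentrations[n] for n in names], dtype=float)
    F = rng.dirichlet(conc, size=cfg.n_samples)  # samples × types
    X = F @ P
    if cfg.measurement_noise_sd > 0:
        X = X * np.exp(rng.normal(0.0, cfg.measurement_noise_sd, size=X.shape))
    sample_ids = [f"sample{i:03d}" for i in range(cfg.n_samples)]
    gene_ids = [f"gene{g:04d}" for g in range(n_genes)]
    return (
        pd.DataFrame(X, index=sample_ids, columns=gene_ids),
        pd.DataFrame(F, index=sample_ids, columns=names),
    )
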