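# Methods

This note documents the models and procedures probcell implements, the
parameters that matter, what the synthetic data emulate (and do not), and
the numerical choices made where the design was genuinely open.

## Debris-augmented classification

**Model.** Multinomial logistic regression over $K$ annotated cell types
plus one synthetic *debris* class. For each annotated reference cell, one
debris row is created by binomial thinning: every count $x_g$ is replaced
by $\mathrm{Binomial}(x_g, 1/f)$ with dilution factor $f = 20$, so
$\mathbb{E}[\text{thinned}] = x_g/f$ per gene and the thinned profile keeps
the cell's composition at debris-like depth. A 1:1 augmentation (one
debris row per cell) keeps class priors interpretable. The model competes
a real shallow type against a low-coverage class with soup-like breadth —
which is exactly the decision a fixed UMI/gene cutoff cannot make.

**Features.** log1p *raw* panel counts, deliberately not library-size
normalized, plus an explicit log1p total-UMI column (on by default).
Depth is the debris class's defining property; normalizing it away would
erase the competing-class signal. The panel is the 1000 most variable
genes of log1p CPM in the reference (bounds model size; stabilizes
transfer across platforms). When a query matrix lacks panel genes they are
zero-filled with a logged warning; above 50% missing the prediction
aborts rather than emit silently wrong probabilities.

**Fitting.** The penalized negative log-likelihood
$-\ell(W, c) + \tfrac{\lambda}{2}\lVert W \rVert^2$ (intercepts
unpenalized) and its analytic gradient are implemented in
`multinomial_objective` and minimized with L-BFGS from a zero start; the
objective is scaled to a per-row mean so the $10^{-6}$ gradient tolerance
is independent of training-set size. The problem is convex, so the fit is
deterministic. The default strength is $\lambda = 1$;
`select_regularization` offers 5-fold cross-validated log-loss over the
grid $10^{-4} \ldots 10^{2}$ when tuning is wanted.

**Calling.** A barcode gets its argmax class when that probability clears
`min_prob` (default 0.5, the majority rule), otherwise `unassigned`.
Exact ties take the first class in model order (deterministic). Debris
and unassigned barcodes are excluded from cell tables but retained in the
audit output. `recovery_report` quantifies what probability calling adds
over a fixed detected-gene cutoff: `fold_vs_cutoff` = called cells /
called cells at or above the cutoff, `+inf` when no called cell clears the
cutoff, `NaN` for an expected type with no calls.

## ADT (antibody capture) thresholding

Present/absent calls use the trough of a Gaussian KDE (Silverman
bandwidth unless overridden) of log1p raw counts: the threshold is the
density minimum between the two highest local maxima. Because integer
counts discretize the low end, shallow spurious maxima occur; the trough
must therefore dip at least 20% below the smaller of the two modes,
otherwise the channel is reported unimodal (invalid, no threshold). A
degenerate (constant) input is flagged rather than thresholded.

## Normalization and state identification

Mean scaling is defined here as multiplicative per-batch per-gene
alignment after depth scaling: (1) each cell is scaled to the median
library size (or an explicit target), (2) log1p, (3) each batch's
detected-cell mean for a gene is scaled onto the pooled detected-cell
mean, with the factor clamped to [0.1, 10] and batches under 10 cells
left untouched (factor 1, warning). Computing means over *detected* cells
only keeps the factor insensitive to batch differences in dropout;
all-zero genes stay all-zero. This removes multiplicative per-gene batch
bias exactly for co-detected genes and is the identity on single-batch
data.

Dimensionality reduction is a gene-centered truncated SVD (default
$d = 30$, standard scRNA-seq practice); cell scores are the right-singular
vectors scaled by singular values, with a deterministic sign convention
(largest-magnitude gene loading positive). States come from cutting a
Ward-linkage tree over the reduced space at $k$ (default 3) — an
automated, reproducible stand-in for manual branch curation. For
cross-species comparison, per-state average profiles from each species are
concatenated on a shared ortholog index and co-clustered with correlation
distance and average linkage; identical states placed under two species
tags merge first, the degenerate sanity case of a one-to-one state
correspondence.

UMAP is treated as a pluggable library-backed embedding (umap-learn, fixed
seed); `svd2` (the first two SVD score columns) is the dependency-free
default used in tests because it is exactly reproducible everywhere.

## Principal-curve pseudotime

Hastie–Stuetzle projection–smoothing on the 2D embedding: initialize with
the first principal-component line; iterate {project points onto the
current 100-point polyline → arc-length $\lambda$; smooth each coordinate
against $\lambda$ with a lowess span of 0.3; re-parameterize by arc
length} until the mean squared projection distance changes by less than
$10^{-4}$ or 50 iterations. $\lambda$ is min-max scaled to [0, 1] so the
axis is relative and the orientation rule is well-defined. On exactly
collinear data the procedure reduces to the PCA projection.

**Orientation.** The curve is flipped when the start marker's
expression-weighted mean $\lambda$ exceeds the *unweighted* mean $\lambda$
of all cells. The comparison point reduces to 0.5 when cells spread
symmetrically along the curve; using the population mean instead of a
fixed 0.5 makes the rule robust when cell density is skewed along the
trajectory, which is the norm rather than the exception. The rule is
idempotent and the anchor gene (e.g. the *SELL* homolog marking "young"
neutrophils) is recorded on the curve.

**Gene pseudotime.** For gene $g$ with weights $w_{cg}$ = normalized log1p
expression (the analysis layer, so one definition of "log expression" is
used throughout): mean $= \sum_c w_{cg}\lambda_c / \sum_c w_{cg}$, SD =
the weighted population form, computed two-pass to avoid cancellation so
a single-support gene returns that cell's $\lambda$ with SD 0. Zero-weight
genes are flagged and omitted from rankings. Rankings are sorted by mean
pseudotime descending with lexicographic tie-breaks, in the two-column
`.rnk` convention consumed by preranked-GSEA tools (the enrichment
algorithm itself is external). Cross-species correlation joins two gene
tables through an ortholog map, keeps one-to-one pairs only (many-to-many
pairs are dropped and counted, avoiding double counting), reports genes
present in one species as margins, and returns the Pearson r of mean
pseudotimes.

## Bulk abundance prediction

Training samples are pseudobulk profiles: per-sample means of normalized
expression over all accepted cells, labelled with the neutrophil fraction
among those cells. Because the pseudobulk of a sample is the
fraction-weighted average of its type means, the feature scale is already
the linear mixing scale, and the model's transform tag is `identity`
(use `log1p` when scoring raw-scale bulk counts). The fraction is
regressed on the linear scale — scores are used for ranking and
stratification, not as calibrated fractions — with an elastic net
(mixing $\alpha = 0.5$, balancing sparsity and stability on correlated
gene features), features standardized, and the regularization path point
chosen by minimum 5-fold cross-validated MSE with seed-fixed folds.
Missing model genes in a bulk matrix are zero-filled below a 50%
threshold, mirroring the classifier's panel rule. Stratification splits
at the median (ties to "lo", deterministic and balanced); a second
variable crosses the split into four hi/lo × hi/lo groups whose table is
exported for external survival tooling.

## Synthetic data: what it emulates, and what it does not

`simulate_reference` draws, per cell type, negative-binomial library
sizes (Gamma–Poisson; overdispersion exercises the depth-sensitive
classifier) and multinomial counts from a type program — a log-normal
baseline over all genes with a boosted disjoint marker block, so types
share a broad background as real transcriptomes do. The default regime
has five types with one shallow neutrophil-like type (mean library 400,
median detected genes < 500) among deep types (mean 5000, median > 1000),
reproducing the regime in which fixed thresholds discard real cells. Type
programs are fixed by a `program_seed` separate from the sampling seed,
so a reference and a query cohort share biology. `simulate_debris` draws
ambient-soup barcodes from the library-size-weighted mixture of all type
programs at totals uniform in (20, 300) — soup-shaped debris is the hard
competing class; uniform noise would be trivially separable. Batch
effects are per-gene multiplicative biases applied to program weights
before sampling, matching the multiplicative correction model.
`simulate_trajectory` drives monotone gene programs with a uniform latent
time (effect size in log2-fold across the axis, default 2);
`simulate_bulk` mixes component profiles with Dirichlet fractions under
multiplicative log-normal noise (default SD 0.1).

Not emulated: sequencing error, barcode collisions, doublets, hierarchical
label taxonomies, platform-specific gene-length or capture biases, or
cross-platform panel mismatch beyond random missingness. Passing tests
therefore show that each stage recovers the structure it assumes at
realistic depths and noise — not that the classifier transfers across
chemistries, which on real data depends on reference quality and panel
overlap.

## Problem sizes and tolerances

The default verification experiment trains on 2,500 reference cells
(5 × 500, 2,000 genes, 1,000-gene panel) and classifies a fresh 10,000
barcode mixture (5 × 1,600 cells + 2,000 debris); trajectory checks use
500 cells × 300 genes; deconvolution checks use 60–100 training profiles
and 200 bulk samples. These sizes give stable statistics while the whole
pipeline re-runs in well under a minute. Numerical tolerances: classifier
gradient $10^{-6}$ (per-row scale), probability sums $10^{-8}$,
batch-mean agreement $10^{-6}$, gene-pseudotime brute-force agreement
$10^{-12}$, SVD orthogonality $10^{-8}$ relative.

## Known limitations

- The mean-scaling formula is one concrete reading of multiplicative
  mean alignment; it equalizes detected-cell means, not full means
  including zeros.
- The principal curve assumes a single non-branching trajectory; it will
  thread branched topologies through their average.
- Abundance scores are relative: they rank samples but are not calibrated
  fractions, and training on classifier calls inherits any calling bias.
- The ADT trough requires genuinely bimodal channels; weak staining with
  a shallow trough (< 20% dip) is reported invalid rather than guessed.
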