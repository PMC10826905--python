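# Methods

## Model

betaimpute treats imputation as simultaneous multiple linear regression on
the logit scale. For a samples × probes matrix X of β-values, probes are
grouped by their exact missingness pattern: the set of sample rows RNA
(size r) at which every probe of the group (columns CNA, size l) is missing.
All probes with no missing value anywhere — m − L of them, where L is the
total number of probes with any NA — serve as predictors for every group.
The blocks A ((n−r) × (m−L), predictors at observed samples),
B ((n−r) × l, targets at observed samples) and C (r × (m−L), predictors at
the missing samples) are complete by construction, and the group is imputed
as

    x   = argmin ‖logit(A)·x − logit(B)‖_F   (minimum-norm solution)
    Imp = logit⁻¹( logit(C) · x )

The model's single substantive assumption is that methylation levels are
strongly linearly related across probes on the logit (M-value) scale, which
holds empirically because inter-sample correlation of methylation is high.
The entire system — predictors included — is transformed to the logit scale
before solving: a linear model is only coherent on an unbounded scale, and
solving with bounded-scale predictors would break the exact-recovery
property on data with perfect logit-linear structure (the fitted wide
system is then consistent for *any* right-hand side, so the min-norm
prediction carries an uncontrolled projection error). The inverse logistic
1/(1+e^{−q}) maps predictions back into (0, 1), so imputed β-values are
always in range. No intercept column is used by default (the logit scale is
centred near 0 for β near 0.5; a config flag can append one).

### Minimum-norm least squares

The solve is a Moore–Penrose pseudo-inverse: thin SVD of logit(A), singular
values below `rtol · σ_max` treated as zero, default
`rtol = 1e-10 · max(p, q)` for a p × q system. Among all least-squares
solutions this picks the one of minimal Frobenius norm, which is what
regularises the typical wide (n ≪ m) methylation system. When the aspect
ratio exceeds 10, the SVD factors are obtained from the eigendecomposition
of the smaller Gram matrix (M·Mᵀ or Mᵀ·M) — algebraically identical,
much cheaper for strongly rectangular blocks; negative eigenvalue round-off
is clipped at zero. A unit test holds both paths to the explicit
`numpy.linalg.pinv` oracle at 1e-10.

### Degenerate inputs

* β of exactly 0 or 1 would give infinite logits: values are clamped to
  [eps, 1−eps] with `logit_eps = 1e-6` (configurable). The clamp is far
  outside the biologically plausible range and preserves monotonicity.
* A group missing in every sample (n−r = 0), or a matrix with no fully
  observed probe (m−L = 0), cannot be imputed. Such groups are left missing
  and reported with a reason, never raised mid-run, so one pathological
  probe cannot abort a chromosome.
* An all-zero system returns zero coefficients.
* Group discovery, set orderings and scheduling are all deterministic
  (ascending indices, label-sorted merges), so identical inputs and seeds
  give bit-identical outputs.

## Chromosome-wise parallelism

Probes are partitioned by annotated chromosome and each part imputed
independently; this shrinks every regression's column dimension and is the
main runtime win even on one core. Parts are dispatched to workers
(joblib/loky) dynamically, largest part first, because runtime is dominated
by the largest chromosome. Each part's random stream is seeded by
`sha256(master_seed : chromosome_label)`, so results do not depend on the
worker count or completion order. Probes absent from the annotation go to
an `unmapped` pseudo-chromosome by default (dropping data silently is worse
than one heterogeneous block); `drop` and `error` policies are available.
When a sample grouping is supplied (e.g. case/control), the matrix is first
split by group and each group imputed entirely from its own rows.

## Mini-batch

For cohorts with hundreds of samples, each regression optionally uses only
P% of the observation rows: per repetition, ⌈rows · P/100⌉ distinct rows
are drawn uniformly without replacement and applied *jointly* to A and B
(they index the same observations); C is never subsampled. The R imputed
blocks are averaged on the β scale. Subsets are drawn independently per
repetition and per pattern group. If the target size already reaches the
row count (always at P = 100), no subsampling happens and the full solve is
returned once — so P = 100 is bit-identical to the full algorithm for any
R. Sensible settings in practice are P ∈ {10, 20, 30} with R ∈ {1, 2, 3}
for n in the hundreds; for small n, keep P high or leave mini-batch off.

## Synthetic data generator

`generate_beta_matrix` draws a logit-scale matrix Z = U·Vᵀ + E with U
(n × k) and V (m × k) standard normal and E Gaussian with sd `noise_sd`,
then maps β = logit⁻¹(Z); probes are assigned to chromosomes in consecutive
blocks of configurable, unequal sizes. This reproduces the one feature the
regression exploits — strong cross-probe linear structure on the logit
scale — and at `noise_sd = 0` makes exact recovery testable: every masked
entry must be recovered to ≤1e-8 (≤1e-6 under 50% mini-batches, which keep
full column rank with high probability at the sizes used).

What it does **not** emulate: probe-type chemistry differences, batch
effects, SNP-affected probes, genomic position (block assignment is
arbitrary), or the bimodal marginal distribution of real β-values. Passing
tests therefore demonstrate the algorithm's correctness and its contracts,
not field accuracy on a particular array product.

`inject_missing` implements the benchmarking protocol: `probe_fraction`
(default 3%) of probes are selected uniformly without replacement; each
receives k ~ Poisson(λ) artificial NAs, k clipped to [1, n] (a selected
probe must lose at least one value and cannot lose more rows than exist —
both edges are vanishingly rare at the intended λ ≪ n), placed uniformly
without replacement among the samples; positions are recorded. With λ = 10
and n = 68 at EPIC scale this masks ≈0.4% of all entries. λ defaults to 5,
a mid-range choice for the double-digit sample sizes used in the test
fixtures (the protocol scales λ with n).

## Evaluation

RMSE and MAE are computed over the artificial-NA positions only — natural
NAs have no ground truth. PCC is the Pearson correlation of (true, imputed)
pairs (undefined, reported as NaN, for degenerate constant inputs). MAPE
divides by the true β, so positions with β < 0.01 are excluded and the
retained count reported; this guards the metric against near-zero
denominators, for which no standard rule exists. Positions a method could
not impute are excluded from all metrics and counted separately rather than
scored as maximal error.

## Problem sizes in tests

The test suite exercises matrices up to 100 × 2000 with 20 replicates for
the accuracy-vs-batch-size trend (the full-scale protocols differ only in
m, and every algorithmic contract — grouping, solving, merging, seeding —
is size-independent). The NA-protocol rate check runs at the full
68 × 816 126 scale, since it needs only mask positions, never the matrix.

## Known limitations

* Predictors are only probes with *zero* missing entries anywhere; heavy,
  scattered missingness shrinks the predictor set rapidly (a column with
  one NA is excluded for all groups). Per-group predictor relaxation is a
  possible extension, deliberately not taken to keep the predictor set
  group-independent.
* One regression per missingness pattern: worst-case cost is one solve per
  NA-containing probe when patterns are all distinct.
* Imputation quality inherits the linearity assumption; structural breaks
  (e.g. mixing tissues without sample grouping) violate it.
* The chromosome split assumes the annotation is right; misannotated probes
  are imputed from the wrong block, silently.
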