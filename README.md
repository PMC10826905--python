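# betaimpute

Missing-value imputation for DNA methylation β-value matrices
(Illumina 450K / EPIC arrays and similar), built around logit-space
multiple linear regression.

## The problem

Methylation arrays report, for each CpG probe and each sample, a β-value in
[0, 1] — the fraction of methylated signal. Quality filtering leaves a
scatter of missing entries, and most downstream tools (differential
methylation, clocks, deconvolution) want a complete matrix. Methylation
levels are strongly correlated across samples, so the missing entries of a
probe are well predicted by a linear model on the other probes — provided
the model is fitted on an unbounded scale.

## The method

Let X be the n × m matrix of β-values (samples × probes), and let L probes
contain missing values. Probes sharing the same *missingness pattern* — the
exact set RNA of r samples at which they are missing — form a group CNA of
l columns and are imputed jointly. With the m − L fully observed probes as
predictors, three complete blocks are cut from X:

- **A** — (n−r) × (m−L): predictors at the observed samples,
- **B** — (n−r) × l: the group's probes at the observed samples,
- **C** — r × (m−L): predictors at the missing samples,

and the regression is solved on the logit (M-value) scale,
logit(p) = log(p / (1−p)):

```
logit(A) · x = logit(B)   →   Imp = logit⁻¹( logit(C) · x )
```

where x is the minimum-norm least-squares solution, computed from a thin
SVD pseudo-inverse (the eigendecomposition of the smaller Gram matrix when
the system is strongly rectangular). The inverse logistic maps every
prediction back into (0, 1), so imputed values are always valid β-values.

Two devices keep this fast at array scale:

- **Chromosome-wise splitting** — probes are partitioned by chromosome and
  each sub-matrix imputed independently (methylation correlation is
  strongest within a chromosome). Parts run in parallel with dynamic,
  largest-first dispatch; results are bit-identical for any worker count.
- **Mini-batch** — for cohorts with hundreds of samples, each regression
  uses only P% of the observation rows of A and B, repeated R times with
  independent subsets and averaged. P = 100 reproduces the full algorithm
  exactly.

The package also ships the evaluation protocol used to benchmark such
imputers: select 3% of probes, give each a Poisson-distributed number of
artificial NAs placed uniformly among the samples, impute, and score RMSE,
MAE, PCC and MAPE on the masked positions only — plus a synthetic generator
of correlated β-matrices so everything is testable without downloads.

## Worked example

```python
import betaimpute as bi

# synthetic 40 x 600 matrix with rank-4 logit structure, two chromosomes
X, ann = bi.generate_beta_matrix(
    n=40, m=600, latent_rank=4, noise_sd=0.1,
    chromosome_sizes={"chr1": 350, "chr2": 250}, seed=7,
)
ds = bi.inject_missing(X, bi.NAGenerationConfig(probe_fraction=0.03, lam=3.0, seed=8))

model = bi.MethylationImputer(ds.observed, annotation=ann)
results = model.fit(workers=1, seed=1)
print(results.summary())

metrics = results.evaluate_against(ds.complete, ds.artificial_mask)
print(f"RMSE {metrics.rmse:.4f}  MAE {metrics.mae:.4f}  PCC {metrics.pcc:.4f}")
```

prints

```
Beta-value imputation results
=============================================
samples x probes        40 x 600
missing entries (input) 47
imputed entries         47
still missing           0
seed                    1
logit eps               1e-06
mini-batch              off

per-part pattern groups:
sample_group chromosome  n_pattern_groups  n_imputed_entries  n_unimputable_groups
         all       chr1                11                 29                     0
         all       chr2                 7                 18                     0

RMSE 0.0172  MAE 0.0123  PCC 0.9983
```

The 47 artificial NAs fell into 18 distinct missingness patterns (one
regression each, 11 on chr1 and 7 on chr2); every entry was imputed, and on
the masked positions the imputations deviate from the hidden truth by 0.017
RMSE — small against the [0, 1] β scale — with correlation 0.998.

The same pipeline is available from the shell:

```sh
betaimpute simulate --samples 40 --probes 600 --rank 4 --noise 0.1 --seed 7 --outdir fixture/
betaimpute impute --input fixture/observed.tsv --annotation fixture/annotation.tsv \
                  --seed 1 --output imputed.tsv
betaimpute evaluate --truth fixture/complete.tsv --imputed imputed.tsv --mask fixture/mask.tsv
```

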