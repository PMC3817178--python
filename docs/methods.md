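# Methods

This note records the statistical model, the numerical choices, and the
design decisions behind the package, in the order data flows through it.

## Probe processing and the stacked matrix

Methylation arrays report paired intensities per CpG locus: `M` (probe
matching the methylated, bisulfite-protected sequence) and `U` (probe
matching the converted, unmethylated sequence). The methylation fraction is

```
β = max(M,0) / (max(M,0) + max(U,0) + offset)
```

with `offset = 100` by default — the platform convention that stabilizes
the ratio at low total intensity. Negative background-subtracted
intensities are clamped at zero; `M = U = offset = 0` is an error. Probes
interrogating fewer than 3 CpGs are discarded. Gene-level summaries are the
**maximum** β over a gene's probes (methylation; the most-methylated locus
is taken to carry the silencing signal) and the **mean** over probe-level
estimates (expression).

The combined matrix stacks expression rows (block `E`) over methylation
rows (block `M`) for the genes in a caller-supplied gene universe (in the
motivating analysis this universe is a transcription-factor-target
restriction; here it is a plain id set, so any restriction can be
expressed). A gene measured on both platforms contributes one row to each
block. M-block entries are `−log(max(β, ε))`, `ε = 1e−3`: a fully
methylated (silenced) gene sits near 0 and a hypomethylated re-activated
gene takes a large positive value that co-varies with its re-activated
expression. The opposite sign (`+log β`) is available as a configuration
for sensitivity analyses, since either orientation is defensible; the
default is the one under which silenced genes load *coherently* (same
direction) with their expression rows in a shared pattern.

Uncertainties: `Σ_E = max(0.1·|signal|, floor)` (a 10%-of-signal error
model) and `Σ_M = max(sd(β)/max(β, ε), floor)` where
`sd(β) = sqrt(β(1−β)/(1+κ))` is the standard deviation of a
`Beta(βκ, (1−β)κ)` variable and the division by β is the delta-method
transfer of that sd to the log scale. `κ = 100` by default (array-level
replicate precision); `floor = 0.01` keeps the χ² likelihood bounded when
β approaches 0 or 1.

## Bayesian non-negative matrix factorization

The model is `D ≈ A P` with `A (rows × p) ≥ 0`, `P (p × m) ≥ 0`, Gaussian
likelihood `exp(−χ²/2)` with `χ² = Σ((D−AP)/Σ)²`, and independent
`Exponential(λ)` priors on every element of `A` and `P` (`λ_A = λ_P = 1`
by default; larger values enforce sparser factors). The exponential prior
is a tractable sparsity-inducing choice standing in for the atomic-domain
prior of the CoGAPS family of samplers; sparsity strength is exposed in
`PriorConfig`.

Conditional on everything else, each element has a conjugate
**truncated-normal** full conditional: for `A_ik`,

```
τ = Σ_s P_ks²/Σ_is²,  b = Σ_s R_is P_ks/Σ_is²  (R = residual without k)
A_ik | · ~ N((b − λ_A)/τ, 1/τ) truncated to [0, ∞)
```

and symmetrically for `P_ks`. Elements within one column of `A` (or row of
`P`) are conditionally independent, so one sweep is `2p` vectorized block
updates — an exact Gibbs sampler, no step-size tuning, updating every
element once per sweep. Truncated-normal draws use the inverse-CDF method
expressed through the upper tail (`x = μ − σ·ndtri(u·Φ(μ/σ))`), which is
accurate for truncation points far into the tail; where the tail mass
underflows entirely the sampler falls back to the asymptotic exponential
approximation of the normal tail. If a pattern row (or amplitude column)
is exactly zero, the paired conditional is the prior itself and is sampled
from it.

`A` and `P` are initialized from the prior with the run's seed; all
randomness flows through a single `numpy.random.Generator` per run, so a
seed fixes the result bit-for-bit. Defaults are 5,000 burn-in and 5,000
sampling sweeps — sized for the package's desk-scale problems (hundreds of
rows, tens of samples), where the chi-squared trace plateaus within a few
hundred sweeps; the configuration accepts arbitrarily larger values.
Posterior means and sds of `A` and `P` are the first two moments over the
sampling sweeps. Scale is not identifiable (`A c · c⁻¹ P`), so every
recovery statement in tests and documentation is in terms of correlation,
never absolute scale.

**Robustness across runs.** Factorizations are repeated over seeds (and
over p, conventionally 2..5). Patterns are matched across runs greedily by
maximum Pearson correlation of `P_mean` rows without replacement (validated
against exhaustive assignment for p ≤ 5); a pattern is *robust* at
threshold 0.8 when its match correlation reaches the threshold in every
pair of runs. Only robust patterns are carried into the downstream summary.

## Meta-pathway activity

Activity of pattern k in sample s is `Z_ks = P_mean,ks / max(P_sd,ks, f)`
with `f = 1e−6` guarding zero posterior sds; each row is rescaled by its
maximum so patterns are comparable on one scale (maximum 1). Rows whose
maximum Z is not positive cannot be rescaled and are flagged instead of
silently normalized. Rescaling is a positive per-row scaling, so every
downstream test statistic on activity is invariant to it.

## Clinical association

Each pattern's activity is regressed on categorical clinical covariates by
OLS. Two contrast encodings are supported: *reference* (dummy coding
against the first sorted level, one model per pattern — the multivariate
form when several covariates enter together) and *one-vs-rest* (one
univariate model per covariate level, testing "activity higher in this
phenotype than everywhere else" — the encoding the pipeline uses to name
each pattern's phenotype). One-sided p-values come from the contrast's t
statistic; the family of simultaneous contrasts of one pattern is adjusted
family-wise with Bonferroni by default (Holm available) — a deliberately
conservative stand-in for single-step simultaneous inference, whose exact
flavor is a configuration rather than a commitment. Constant activity rows
return estimate 0 and p 1; rank-deficient designs raise an error naming
the collinear covariates. Preconditions (≥ 2 levels, ≥ 3 samples per
level) are validated before fitting.

The comparator clusters samples on `1 − Pearson` correlation distance with
average linkage (configurable: complete/ward), cuts the tree at each
k = 2..6, and tests each cut against each clinical variable with a Fisher
exact test: the exact hypergeometric test for 2×2 tables, exact enumeration
of all tables with the observed margins for r×c tables with total ≤ 30,
and otherwise a seeded Monte-Carlo permutation null (10⁵ draws) on the
generalized hypergeometric table probability. Degenerate tables (single
cluster or single phenotype level) return p = 1 with a warning.

## Gene-set enrichment

For genes present in both blocks, the pattern amplitudes are combined by
inverse-variance weighting: `w = 1/sd²`, `Â = (w_E A_E + w_M A_M)/(w_E+w_M)`,
`sd(Â) = (w_E + w_M)^{−1/2}` — the minimum-variance unbiased combination,
never worse than either input. Genes on one platform pass through
unchanged. Under the default `−log β` convention, methylation amplitudes
already point the same way as expression amplitudes for silenced genes, so
no sign flip is applied in the weighting.

A gene set G is scored with `Z_G = (1/√|G|) Σ_{g∈G} Â_g/sd_g`. The null is
*competitive*: `n_perm` random same-size gene sets drawn without
replacement from the scored universe (seeded), and
`p = (1 + #{null ≥ Z_G})/(n_perm + 1)` — ties count as extreme, so p is
valid and bounded below by `1/(n_perm+1)`. A consequence worth knowing:
constructions where null draws can tie the observed statistic exactly
(e.g. a single-gene set whose gene can be re-drawn) get p inflated by the
tie rate, by design. Benjamini–Hochberg is applied across sets within a
pattern, optionally within caller-declared strata (e.g. one adjustment per
source database). Enrichment is one-sided (high amplitudes); a depletion
mode scores the left tail.

## Marker statistics

Welch (unequal-variance) t-tests are used throughout; the equal-variance
pooled test is a flag away. Probe-level differential expression tests each
probe of a candidate gene per group contrast one-sidedly against normal
samples and summarizes per gene by the minimum p over probes (sensitive to
isoform-specific activation) plus the difference of log-scale group means.
The outlier rule flags a tumor sample when its value is at least
`max(normal values) + 0.5` on the log2 scale (the threshold and the log
base are configurable; the boundary is inclusive, and flags are monotone
in the threshold). ΔCt statistics: `ΔCt = Ct_target − Ct_reference` per
sample, `ΔΔCt = mean ΔCt(tumor) − mean ΔCt(normal)`, fold change
`2^(−ΔΔCt)`; the one-sided test for overexpression is *lower* ΔCt in
tumors; samples missing a Ct are dropped with a warning. Count-matrix
tests operate on `log(count + 1)` (natural log; the base shifts t
statistics by a constant factor and the pseudo-count only matters for
low-count genes).

## The synthetic generator

The generator emulates the shape of a two-platform discovery cohort:
default group sizes 25 normal / 13 HPV-positive / 31 HPV-negative (69
samples), 120 expression genes, 100 methylation genes, 60 shared — gene
counts an order of magnitude below a real array panel so that the full
pipeline runs in seconds.

Planted structure, in the order it is built:

- **Patterns** `P_true (p × m)`: each pattern is elevated in exactly one
  group — `U(0.8, 1.2)` within the group for sample heterogeneity — and is
  exactly zero elsewhere. Zero background is deliberate: inactive samples
  carry *no* pattern activity, the decay-to-zero structure the uncertainty
  model is designed to detect, and the regime in which the posterior
  Z-score cleanly separates active from inactive samples.
- **Expression**: each gene has one dominant pattern (loading `U(2,4)`) and
  small background loadings (`U(0,0.3)`); log expression is `A_E P_true`
  plus Gaussian noise with sd = (planted-signal sd)/snr, so `snr` is
  directly interpretable; the matrix is exponentiated to positive scale.
- **Methylation**: a fraction of the shared genes (default 0.5) is
  *silenced*: their methylation mean is `μ = 0.9·exp(−a·t)` with `t` the
  0–1-clipped pattern value and `a = log(0.9/0.1)`, i.e. β falls from 0.9
  to 0.1 exactly where the gene's expression pattern rises — the planted
  anti-correlation. The log-linear form makes `−log μ` affine in the
  pattern, so the methylation block has the same non-negative factor
  structure as the expression block and the planted amplitudes are exact
  on the stacked-matrix scale. Methylation-only genes (labelled `TF*`,
  transcription factors measured only on the methylation platform) carry
  the same pattern-linked hypomethylation; unsilenced shared genes get
  flat methylation (`U(0.3, 0.7)` per gene). Observed β is
  `Beta(μκ, (1−μ)κ)` with precision κ = 100.
- **Probes**: one retained probe per gene (3–8 CpGs) with `M = s·β`,
  `U = s·(1−β)` and lognormal total intensity `s` (median 20,000, log-sd
  0.2) — scales at which the offset-100 β formula round-trips to within
  0.02 — plus, for about half the genes, a 1–2-CpG probe carrying pure
  noise that the CpG filter must remove.
- **Clinical covariates**: group (and derived tumor/HPV columns), with
  gender, smoking and site randomized — associated with nothing by
  construction.
- **Gene sets**: planted enriched sets are drawn from the top decile of a
  pattern's planted amplitudes; null sets uniformly from the universe.

What the generator does **not** emulate: batch and dye effects, probe
cross-hybridization, copy-number contamination of either platform,
sample-level quality variation, correlated noise between genes, or
realistic gene-gene covariance within sets. Tests passing on this
generator therefore demonstrate the *algorithmic* contract (recovery,
calibration, determinism) under the planted model, not performance on
arrays with those artifacts.

## Problem sizes and tolerances used by the checks

The recovery checks run at 200 stacked rows × 60 samples (3 groups of 20),
snr 10, 5,000+5,000 sweeps across 5 seeds — sizes chosen so the full suite
runs in about a minute while leaving the conclusions unchanged at larger
scale. Calibration checks use 200 association replicates and 100 null gene
sets at 1,000 permutations. The Fisher route is compared against an exact
rational-arithmetic enumeration oracle over all 19,274 2×2 tables with
positive margins and total ≤ 24 (agreement to 1e−10; observed ~3e−16).
The end-to-end pipeline is rerun twice with identical configuration and
compared byte-for-byte.

## Known limitations

- The exponential-prior Gibbs sampler is not the atomic-domain sampler it
  stands in for; posterior sds (hence activity Z-scores) inherit some
  scale-coupling between `A` and `P`, which compresses Z contrasts when
  patterns do not decay to zero.
- Exact r×c Fisher enumeration is exponential in table size and is capped
  at total 30; beyond that the Monte-Carlo p has simulation error
  ~1/√draws.
- The permutation null resamples gene labels (competitive null); it does
  not preserve gene-gene correlation, the standard caveat of that choice.
- `+log β` sensitivity mode is provided but the shipped defaults and tests
  exercise the `−log β` orientation.
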