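# Methods notes

This note records the statistical model behind each stage, the defaults and
why they are what they are, what the simulator does and does not emulate,
and the numerical conventions a maintainer would otherwise have to reverse-
engineer from the code.

## Harmonization

Cohorts arrive as feature×sample matrices on three platform classes.
`processed_array` and `raw_array` (summarized intensities) are
quantile-normalized within the cohort; `rnaseq` is log2(x+1)-transformed
when still linear (the +1 pseudo-count is configurable; it is the common
choice for TPM-like values). Probe-level preprocessing of raw arrays
(CEL parsing, background correction, RMA summarization) is out of scope by
design: raw-array cohorts must be supplied at one-value-per-feature scale.

Quantile normalization maps each column's values to the row-wise mean of
the column-sorted matrix at their within-column rank; ties receive the mean
of the target values at the tied positions, the convention of the standard
microarray pipelines. The operation is idempotent and equivariant under
column permutation, which the suite asserts.

Probe collapse keeps, per gene, the probe with the largest sample variance
(ddof = 1) in that cohort; variance ties break to the lexicographically
first probe id so results are machine-independent.

Standardization is per cohort and per gene against the cohort's *primary
tumor* samples only: subtract the reference mean, divide by the reference
SD (ddof = 1, the convention of the surrounding ecosystem). Normals and any
other non-reference samples are transformed with the same parameters, so
"0" always means "average primary tumor of this dataset". Genes with any
missing value or zero reference SD in a cohort are dropped from that cohort
before the strict cross-cohort gene intersection. Standardization is
idempotent to 1e-9.

A caveat worth knowing: under global differential expression (here, a
planted module in half the samples), quantile normalization redistributes a
small amount of class-correlated signal into unrelated genes, measurably
inflating the false-positive fraction of the downstream gene selection.
This is a property of the method, not of this implementation; it is why the
planted-recovery checks pool the simulated gene-level cohorts by
standardization alone, and why on real array data the q-gate should be
read as approximate.

## Median split

The cutoff is the median of the pooled tumor expression of the target gene;
samples strictly above are `high`, ties and below are `low` (a deterministic
tie policy; with continuous data ties are measure-zero). Normals are
labelled against the tumor cutoff so the tumor-vs-normal contrast can be
expressed on the same dichotomy. An all-constant series is a degenerate
split and raises.

## Association battery

Odds ratios are `(a·d)/(b·c)` on the 2×2 of feature vs class, oriented as
odds of the feature in the high class. Confidence intervals use the Woolf
log method `exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d))`; p-values come from the
two-sided Fisher exact test. A zero cell triggers the Haldane–Anscombe
+0.5 correction for the OR/CI (flagged in the result); the exact p is
always computed on raw counts. Multi-level variables get per-level
target-vs-rest ORs and an overall chi-square over the full R×2 table.
Continuous variables use the Welch t (unequal variances — the safer default
where group variances are unknown); more than two groups use the classical
one-way ANOVA F-test. Samples missing a variable are dropped for that
variable only.

## Moderated t and gene selection

The variance model is the standard hierarchical one: `s_g² | σ_g²` is
`σ_g²·χ²_d/d` with `d = n₁+n₂−2`, and `σ_g²` is scaled-inverse-chi-square
`(d₀, s₀²)`. The prior is fit by method of moments on `z_g = log s_g²`
through digamma/trigamma identities; the trigamma inverse uses the Newton
iteration that converges quadratically from `0.5 + 1/x`. When the observed
spread of `z` is at or below its theoretical value at `d₀ = ∞`, the prior
degrees of freedom are infinite and every gene is shrunk fully to `s₀²`;
when all variances are literally identical, `s₀²` is that common value.
`d₀ = 0` reproduces the classical pooled two-sample t exactly, which the
suite asserts at machine precision, and the whole fit matches the
Bioconductor limma reference to ~1e-8 (cross-checked through Rscript).

P-values use the t distribution on `d₀ + d` df, with `∞` represented by a
1e6-df cap. Zero-variance genes are assigned p = 1 and flagged rather than
propagating NaNs. The fold-change gate `|log2fc| > log2 1.25 ≈ 0.3219` is
applied on the standardized log2 scale — the only scale that exists after
pooling; this reading of the linear 1.25× threshold is a documented
interpretation. Selection requires all three gates (p, BH q, FC) and is
strict at the boundary. BH q-values are delegated to statsmodels'
step-up implementation and verified in the suite against a brute-force
O(m²) evaluation of the definition.

The learning/validation partition designates one cohort as the learning
set (default: the largest), mirroring the practice of training on the
single biggest series and validating on the pooled remainder.

## Signature

The centroid is the per-gene *median* over high-class learning samples of
the selected genes (medians resist the heavy tails that survive
standardization). Classification is the sign of the Pearson correlation
between a sample's vector over the signature genes and the centroid;
`r = 0` breaks to `low_like` (deterministic, measure-zero). Correlation
sign is invariant to positive affine rescaling of the sample, so calls
depend only on expression pattern. Genes are matched by id, never by
position; validation sets missing ≤10% of signature genes fall back to the
intersection, more is an error. Models persist as JSON with a SHA-256
provenance hash that is verified on load.

## Survival

Kaplan–Meier estimation, the k-group log-rank test and Cox partial-
likelihood maximization are delegated to lifelines (Efron tie handling,
Wald p-values); the module adds plain Greenwood variance intervals for
rates at fixed horizons (the five-year rate is read at 60 months),
collinearity detection before fitting, dummy coding of categoricals against
the first level, and product-term interactions. Time stratification
episode-splits each subject at 6 and 12 months and fits a start–stop Cox
model with one covariate×interval indicator per interval; an interval
without events reports NaN rather than failing. The univariate→multivariate
screen admits covariates at p < 0.05 exactly. Episode-splitting is one
reasonable choice of time-dependent analysis, not the only one.

## Simulator

The generator draws, on the log2 scale: per-gene baseline means N(7, 1);
per-gene variances from scaled-inverse-chi-square (d₀ = 4, s₀² = 0.25 by
default — dispersed enough that the EB prior is estimable and recoverable);
a latent anchor level N(0, 1) per tumor whose position against the cohort
median defines the true class; the observed anchor as latent plus N(0,
`anchor_noise_sd`); module genes shifted by ±`module_log2fc` in true-high
samples (half up, half down, as real signatures contain both directions);
and cohort effects applied *after* biology — a per-cohort per-gene location
shift N(0, `cohort_shift_sd`) and a per-cohort scale factor drawn from
`cohort_scale_range` around the gene grand mean.

Binary covariates are Bernoulli with class-conditional rates chosen so the
odds ratio against the true anchor class equals the target: baseline
prevalences and ORs default to the clinicopathological table of the pooled
ovarian series (serous 0.89/2.45, FIGO III–IV 0.85/1.71, high grade
0.71/1.45, macroscopic residue 0.66/1.10, platinum sensitivity 0.88/1.03,
TP53 0.97/1.17). Molecular subtype labels are multinomial at the series'
observed frequencies and independent of the anchor.

Survival is exponential proportional hazards: OS rate 0.015/month at
baseline (median ≈ 46 months, matching the ~45-month median of the target
population), PFS at 1.6× that rate, and the module-high class multiplied by
`signature_hr` (default 0.71, the planted protective effect). Censoring is
an independent exponential with rate tuned so the expected censored
fraction equals `censor_rate`, capped at 243 months of follow-up —
the simplest mechanism satisfying the non-informative-censoring assumption
of KM/Cox.

Normals (default 30) carry the anchor shifted down by
`normal_anchor_offset` (default 2 log2 units; the true tumor-vs-normal
effect size is not pinned by the association surface, so it is exposed as a
parameter). They are generated inside the first cohort — sharing its batch
effects — because a normals-only cohort would have no primary-tumor
reference to standardize against; this also matches how normals appear
inside public series.

Randomness is one `SeedSequence` per run with per-stage child streams
spawned in a fixed order, so identical configs give identical outputs and
adding samples to one stage does not perturb another.

What the simulator does **not** emulate: probe-level raw intensities,
platform-specific intensity distributions, correlated gene–gene structure
beyond the planted module, subtype-dependent biology, informative
censoring, or any relation between covariates and survival other than
through the module class. Passing tests therefore demonstrate the
pipeline's correctness and calibration under its own assumptions, not
robustness to everything real cohorts do.

## Problem sizes used in the checks

The suite validates estimator calibration at deliberately modest sizes
chosen to give stable Monte-Carlo answers: EB-prior recovery on 10,000
genes × 50 replicates; Cox calibration on 50 studies of n = 1500 and
coverage on 200 studies of n = 500; planted-signature recovery on one
2000-gene study with a 150-gene module and a 150/150 learning split; the
acceptance script averages the validation-arm hazard ratio over 48
replicate studies because a single ~450-sample validation arm carries a
±0.09 standard deviation on the HR estimate.

## Known limitations

- RMA is not reimplemented; raw Affymetrix cohorts must arrive summarized.
- The q-gate's nominal FDR is approximate downstream of quantile
  normalization (see above).
- The Woolf CI is slightly narrower than exact conditional intervals for
  extreme tables; point estimates are unaffected.
- Cox models here use complete cases per model; no imputation.
- The correlation-sign classifier emits hard calls only; no probabilistic
  score beyond `r` is defined.
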