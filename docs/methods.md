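# Methods

This note records the statistical models the package implements, the
assumptions and defaults behind them, what the synthetic-data generator
does and does not emulate, and the numerical and design choices that were
genuinely open.

## Study design and data model

The pipeline targets a three-arm plasma-EV small-RNA design: healthy
controls (HC), and patients sampled before (PreOp) and shortly after
(PostOp) surgical tumor removal, with paired patient samples. Input is
either aligned reads (SAM/BED6) plus multi-source annotations
(GTF/GFF3/BED6, each record carrying one of ten RNA biotypes) or a
precomputed feature × sample count table, plus a sample sheet with
subject, group and per-patient clinical variables.

### Read assignment

Overlapping annotations are resolved per read by a fixed biotype priority
(miRNA > tRNA > rRNA > mRNA > pseudogene > snRNA > snoRNA > piRNA >
lncRNA > miscRNA), then largest read–feature overlap, then smallest
feature id. The rule makes assignment a total, deterministic,
order-independent function; the suite checks it against a brute-force
scan-and-sort resolver on 10,000 randomized instances. Reads must match
feature strand (small-RNA protocols are stranded; `stranded=False`
relaxes this), must overlap by ≥ 1 base (`min_overlap`), and must be
single-hit — duplicate read ids are an error, since multi-mapper
rescue belongs upstream of this package. Coordinates are 0-based
half-open internally; GTF is converted at the boundary.

### Within-biotype normalization

`norm(f,s) = counts(f,s) / T(b(f),s) × 1e6` where `T(b,s)` is the total
reads of biotype `b` in sample `s`. The same totals enter the GLMs as
offsets `log T(b(f),s)`, so the tested quantity is a feature's share of
its own biotype. Rationale: biotype-level composition genuinely shifts
with disease state, and a library-wide normalization would propagate that
shift into every feature of every biotype. If `T(b,s) = 0` the features
of that biotype are treated as missing in that sample (masked out of the
fit, NaN in the normalized matrix) with a logged warning.

## Differential expression

Per feature, counts follow `NB(μ_fs, φ_f)` with `Var = μ + φ μ²` and
`log μ_fs = x_sᵀ β_f + log T(b(f),s)`. Designs: intercept + group
indicator (PreOp vs HC), optionally + subject indicators (paired
PreOp vs PostOp; the subject effect is shared between a patient's two
samples by construction of the generator, which is what justifies
blocking). Fitting is Fisher-scoring IRLS, vectorized across features
(batched normal equations, tiny ridge 1e-8 for degenerate features,
max 50 iterations, relative deviance tolerance 1e-8, μ clipped to
[1e-8, 1e12]).

**Dispersion.** For each candidate φ on a 22-point log grid spanning
1e-6–10, the Cox–Reid adjusted profile log-likelihood
`APL_f(φ) = ℓ_f(β̂(φ), φ) − ½ log det(Xᵀ W X)` is evaluated with
warm-started IRLS. Each feature maximizes
`APL_f(φ) + (prior_df / resid_df) · mean_f APL_f(φ)` — empirical-Bayes
shrinkage toward the common dispersion with prior weight `prior_df = 10`
— and the grid argmax is refined by parabolic interpolation in log φ.
Estimates are floored at 1e-6. Recovery checks: median estimate within
±20% of a generating φ = 0.3 (2,000 features, 60 samples) and ≤ 0.02 on
Poisson data.

**Quasi-likelihood F-test.** With the shrunk φ̂_f fixed, full and reduced
models give deviances `D_f` and `D_f⁰`. The feature-level
quasi-dispersion `s²_f = D_f / df_res` is shrunk toward the across-feature
mean with `d0 = 10` prior df, and
`F_f = (D_f⁰ − D_f) / s²_{f,shrunk}` is referred to `F(1, df_res + d0)`.
Non-convergent fits are flagged and reported at p = 1. Under a seeded NB
null (2,000 features, 30 vs 30, φ = 0.3) the empirical type-I error at
α = 0.05 is ~0.04–0.05 and the p-value distribution is uniform (KS <
0.05); p-value ranks agree with per-feature ML negative-binomial
likelihood-ratio tests (Spearman > 0.99 across a 500-feature effect
grid).

**Reporting.** log₂FC = log₂((m̄_A + c)/(m̄_B + c)) on normalized group
means with prior count `c = 2`, which keeps "detected only in cases"
fold changes finite (they land around 8–14 at default simulation
abundances). BH correction is applied within each biotype's test family
by default (`bh_per_biotype=False` for a global family); significance is
adjusted p ≤ 0.05 and |log₂FC| strictly > 1. Features with < 1 read in
< 3 contrast samples are prefiltered.

## Discovery and per-marker metrics

Candidates are the feature-id intersection of (significant up, PreOp vs
HC) and (significant drop, PreOp → PostOp). Detection sensitivity is the
fraction of PreOp samples with raw count ≥ 1 (threshold configurable);
specificity the fraction of HC samples below it. "Not detected" is read
as a raw zero, hence detection works on raw counts while the per-marker
AUC — Mann–Whitney concordance with ½ for ties — uses within-biotype
normalized abundance, consistent with everything downstream of
normalization.

## Panel models

Predictors are `log1p(biotype-CPM)`. The final model is maximum-
likelihood logistic regression (Newton/IRLS, verified against an
independent implementation to 1e-6); under complete separation it is
re-fit with a light L2 penalty (λ = 1e-3) and flagged.

**Selection.** Greedy backward elimination minimizes AIC, removing the
marker whose removal most decreases it until no removal helps, ties to
the smallest marker id. All candidate subsets are compared under a
single L2-stabilized objective (λ_select = 1): tumor-specific markers
are zero in every control, so most subsets separate the training labels
perfectly; comparing unpenalized fits would leave every separating
subset at log-likelihood ≈ 0 and reduce "model choice" to tie-breaking,
while a unit penalty leaves likelihood differences that genuinely rank
subsets. A Wald-p-based elimination (`criterion="wald"`) is available.

**Validation.** LOOCV re-fits coefficients per fold with the marker set
fixed (the fully nested variant that re-runs selection per fold is
available via `reselect=True`; the fixed-set default measures coefficient
stability, not selection stability, and is therefore optimistic about the
selection step). ROC summaries: trapezoid AUC (= concordance), DeLong
variance CI (truncated to [0,1], untruncated bounds also reported, since
normal-approximation CIs of high AUCs legitimately exceed 1), two-sided
Mann–Whitney p against AUC = 0.5 (exact when both classes ≤ 10 and
tie-free), Youden-optimal operating point.

Two biases worth knowing about. (1) Pooled LOOCV scores are
pessimistic under the null: leaving out a sample nudges the refit model
away from that sample's label, and when predictor rows are near-constant
the out-of-fold scores become intercept-driven and *anti-rank* the
labels — the permutation-null LOOCV AUC can fall far below 0.5. Tests of
the permutation null therefore use marker sets with real across-sample
variation and assess the distribution's center, not a single draw.
(2) Fixed-set LOOCV inherits selection bias when the marker set was
chosen on the full data; on permuted labels this inflates the apparent
AUC. Both effects are properties of the procedures, not of this
implementation.

## Clinical module

Dichotomization rules: ER/PR/E-cadherin as recorded; grade 3 vs 2; Ki-67
split at 14%; T stage ≥ 3; HER2 positive = IHC score 3 only by default —
IHC 2 is equivocal without in-situ-hybridization confirmation — with a
`"2+3"` rule available. Associations use rank-sum tests on PreOp
(pre-treatment) normalized abundance only, BH-corrected; groups smaller
than 3 are skipped with a warning. Status-prediction panels reuse the
panel machinery with patients as units.

## Synthetic-data generator

Per sample, expected relative abundances follow a two-component mixture:
`p = (1 − τ_i) · baseline + τ_i · tumor_i`, with τ_i ~ Beta(2, 8) per
patient (low mean, heavy tail — the tumor-derived fraction of plasma EVs
is plausibly small and variable; no literature estimate exists, so this
is a placeholder chosen once), τ replaced by `r·τ_i` after surgery
(`postop_residual r = 0.1`). Baseline composition uses the observed
plasma-EV biotype shares (lncRNA 28.3%, mRNA 27.3%, piRNA 19.9%, miRNA
18.6%, minor classes sharing the remainder) with lognormal feature
weights within biotype. The tumor component re-weights biotypes
(miRNA/snRNA/snoRNA/tRNA ×2, lncRNA ×0.4 by default) and assigns each
planted marker the tumor expresses a fixed 0.5% share of tumor reads.
Planted markers have zero baseline abundance — tumor-specific, hence
never detected in controls — and each patient's tumor expresses each
marker independently with probability ρ = 0.2, putting single-marker
sensitivity near 0.2 at specificity 1. Counts are NB (φ = 0.3 default,
per-biotype override) around `libsize × subject_effect × p`, with
lognormal library sizes (mean 1.3 × 10⁶ mapped reads, CV 0.3) and a
lognormal subject effect (SD 0.2) shared between a patient's paired
samples. Clinical variables are assigned with cohort-realistic marginals
(exact counts at n = 32, largest-remainder rounding otherwise),
independent of τ; optionally a subset of planted markers is carried only
by ER-positive (or HER2 IHC-3) tumors.

The read-level fixture draws reads feature-first from the baseline
composition, places them uniformly inside feature bodies on the feature's
strand, and resolves each read's truth label with an independent
brute-force application of the priority rule — so a read emitted by a
lncRNA but landing in an embedded miRNA is truthfully labeled as the
miRNA.

The panel fixture (`simulate_panel_markers`) emulates a *complementary*
marker panel: each case expresses 1 + Poisson(0.5) of the 8 informative
markers, drawn without replacement — subtype-restricted, largely
non-overlapping expression, mean per-marker sensitivity ≈ 0.19 at
specificity 1. Complementarity matters: under independent Bernoulli
carriage most markers have no *unique* case coverage, and AIC elimination
then correctly prunes them as redundant — full-panel recovery is not an
attainable (or desirable) outcome in that regime.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no sequence content, read-length or adapter
artifacts; no multi-mapping; no correlation between clinical covariates
(real ER/PR/HER2/Ki-67 are strongly dependent); no batch or extraction
effects; feature-independent NB noise (no gene–gene correlation beyond
the mixture structure); tumor profiles differ between patients only
through carried markers, not in their non-marker composition.

## Problem sizes and determinism

Tests and the acceptance script run at the study's sample sizes (30 + 32
paired) with 500–2,000 features, 20-replicate panel-recovery batches and
a 2,000-feature null calibration — sizes chosen so each claim is tested
at meaningful power while the whole suite stays desk-scale. All
randomness flows from explicit seeds through `numpy.random.SeedSequence`
spawns; identical (config, seed) reproduces every output byte-for-byte,
and the pipeline manifest records the config hash (output-path
independent) and seed.

## Known limitations

- The QL F-test's deviance-based quasi-dispersion is slightly
  conservative at very small means; the prefilter keeps that regime out
  of the default analysis.
- Composite/readthrough loci (reads overlapping two genes) are treated
  as ordinary features; identical-rank identical-interval candidates are
  disambiguated by id suffixing at annotation merge, not biologically
  resolved.
- Backward elimination is greedy; with strongly collinear markers the
  retained set is one of several near-equivalent panels, and alternative
  panels of equal performance should be expected on resampled cohorts.
- No survival analysis, GO enrichment, or molecular subtyping; those sit
  outside the package's scope.
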