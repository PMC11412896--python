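# Methods

`stratewas` implements the statistical core of a sex-stratified
epigenome-wide association (EWAS) meta-analysis: per-stratum probe-wise
linear models, correction of test-statistic bias and inflation, fixed- and
random-effects inverse-variance pooling across cohorts and sex strata,
autocorrelation-corrected region calling, polymethylation risk scoring, and
a power simulation contrasting sex-adjusted with sex-stratified designs.
This note records the models, their assumptions, the defaults that matter,
and the design choices made where the design was genuinely open.

## Probe-wise EWAS

For each CpG probe, the methylation beta value (a fraction in [0, 1]) is
regressed by ordinary least squares on case/control status plus covariates
(age in years, a methylation-derived smoking score, five of six blood
cell-type proportions — granulocytes serve as the reference since the six
sum to one — and batch dummies). Sex enters as a covariate only in the
sex-adjusted model; male-only and female-only runs restrict the samples and
drop the sex term. Probes on chrX/chrY are excluded before fitting. The
design matrix is shared across probes within a run, so all coefficients,
residual variances and t-statistics come from one vectorized
normal-equations solve; t-tests use n − p degrees of freedom. Effects and
standard errors are reported multiplied by 100, i.e. as percentage points
of methylation difference between cases and controls.

An optional empirical-Bayes moderation (off by default) shrinks the
per-probe residual variances towards a common scaled inverse-chi-square
prior fitted by matching moments of log s²; the posterior variance
(d₀s₀² + d·s²)/(d₀ + d) replaces s² and the t reference gains d₀ degrees of
freedom. The default stays plain OLS so every reported number is an
elementary closed form.

The interaction model adds sex and status×sex terms and reports the
interaction coefficient: with sex coded 1 = male, the status main effect is
the female case effect and the interaction is the male-minus-female
difference.

Genomic inflation λ is the median association chi-square divided by the
null median of χ²₁ (`scipy.stats.chi2.ppf(0.5, 1)` ≈ 0.4549); the exact
median is used rather than a rounded constant so that a batch of p = 0.5
everywhere gives λ = 1 identically.

Missing covariate values cause listwise sample deletion (logged), never
imputation. "Methylation PCs" as used in large consortium analyses are out
of scope here; when needed they can be passed as ordinary numeric covariate
columns.

## Bias/inflation correction

The vector of z-statistics (effect/SE) from one EWAS is modelled as a
three-component Gaussian mixture: a dominant null component N(μ₀, σ₀²)
flanked by two alternative components. μ₀ is the *bias* and σ₀ the
*inflation*; corrected statistics are (z − μ₀)/σ₀, equivalently
effect − μ₀·se with se scaled by σ₀, and p-values are recomputed two-sided
against the standard normal. The correction is exactly invertible and
rank-preserving.

The fit is multi-start EM (default 10 starts; each start gets a short run
and the best is refined until the per-observation mean log-likelihood
changes by < 1e-8, capped at 500 iterations). Admissibility at the
solution requires μ₁ < μ₀ < μ₂ and π₀ ≥ 0.5; the null is identified as the
component with the largest mixing proportion, ties broken by smallest
|mean|. Two numerical guards matter:

* alternative means are constrained to at least 3 null-SDs from μ₀
  (mirroring the informative priors of the Bayesian sampler formulation of
  this mixture); without it, on a signal-free batch the flanking
  components bite into the null's tails and deflate σ₀ by ~2%, which is
  exactly the size of the calibration being corrected;
* component SDs are floored at 1e-3 and mixing proportions at 1e-8 to
  prevent collapse.

The reference formulation samples this mixture by Gibbs; EM is used here
for determinism (the fit is seeded) with the same estimands. On synthetic
batches of 50,000 statistics, injected (bias 0.3, inflation 1.4) is
recovered within ±0.03 and the post-correction λ lies in [0.97, 1.03].

## Meta-analysis

Fixed effect: weights wᵢ = 1/seᵢ², pooled effect Σwe/Σw, SE 1/√Σw.
Random effects: DerSimonian–Laird, with Q = Σw(e − ê_FE)²,
τ² = max(0, (Q − (k−1))/(Σw − Σw²/Σw)), starred weights 1/(se² + τ²), and
I² = max(0, (Q − (k−1))/Q). p-values are two-sided normal; no
Hartung–Knapp adjustment and no REML, keeping every quantity a closed
form. se_FE ≤ se_RE always, with equality iff τ² = 0.

Four modes mirror the study designs: sex-adjusted (one whole-cohort table
per cohort), male-only, female-only, and sex-stratified (both sex strata of
every cohort enter as separate studies — 8 tables for 4 cohorts). The
larger study count is carried by the per-probe k column. Probes are pooled
when present in at least `min_cohorts` (default 2) input tables; corrected
columns (`effect_bc`/`se_bc`) are used when present. Significance is
flagged at 2.4e-7 and 3.6e-8, the array-wide and genome-wide conventions
for 450K-scale data.

Combining the published female and male pooled estimates for the two
worked-example CpGs (0.66 ± 0.16 with 0.67 ± 0.14, and 0.90 ± 0.22 with
0.69 ± 0.18) under the fixed-effect rule reproduces the published
sex-stratified columns (0.67 ± 0.11 and 0.77 ± 0.14) at two-decimal
rounding; this is frozen as an acceptance check.

## Region calling

A comb-p-style chain, fully deterministic:

1. **ACF** — Pearson correlation of signed per-probe z-scores between
   probe pairs, binned by genomic distance (50 bp bins to 750 bp).
   Correlations are clipped to [0, 1) and made non-increasing in distance
   by pair-count-weighted isotonic (pool-adjacent-violators) regression;
   empty bins carry zero weight so they cannot drag populated bins down.
2. **Smoothing** — each probe's p-value is replaced by the two-sided p of
   the Stouffer–Liptak–Kechris combined z over all probes within 750 bp on
   the same chromosome: z_comb = Σz/√(m + 2Σσ_jk), σ from the ACF at the
   pairwise distance. Probes without neighbours keep their input p.
   Signing is z = Φ⁻¹(1 − p/2)·sign(effect), so only directionally
   consistent neighbourhoods combine strongly; unsigned probes fall back to
   Φ⁻¹(1 − p).
3. **Regions** — maximal runs of smoothed p < 0.001 with inter-probe gaps
   ≤ 750 bp, same chromosome; runs of fewer than 4 probes are discarded.
4. **Scoring** — Stouffer–Liptak over the region's *raw* p-values with
   ACF covariances; Sidak correction
   p_sidak = 1 − (1 − p_region)^(total_tested_bases/region_bases), where
   total_tested_bases is the summed per-chromosome probe span and the ratio
   is floored at 1 so p_sidak ≥ p_region even for a region spanning an
   entire tested chromosome. Called regions need p_sidak < 0.05.

The effective-test count by covered-bases/region-width is the single
largest reimplementation choice (the convention of the established comb-p
tool); probe-count-based alternatives give systematically different Sidak
levels. Coordinates are 1-based inclusive in memory and in the native TSV;
only the BED writer converts to 0-based half-open. Peak extension uses the
seed threshold itself.

Because smoothing spreads signal to every probe within 750 bp, a planted
cluster in a *dense* probe field recruits flanking probes into the called
region; recovery fixtures therefore isolate planted clusters by ≥ 800 bp so
exact-region assertions are well defined. On null tables of 10,000 probes,
zero Sidak-significant regions are called in ≥ 19/20 replicates.

## Polymethylation scores

Construction on a target cohort, given training summary statistics:

1. **Co-methylated regions** — maximal runs of adjacent probes (gap
   ≤ 1,000 bp) where every consecutive pair has squared Pearson correlation
   strictly greater than 0.3 across samples, computed on
   covariate-residualized betas when available. The genomic-background
   density criterion of the original sliding-window method is simplified to
   this max-gap rule. Singletons are not regions.
2. **Pruning** — each region keeps only its probe with the smallest
   training p (ties: smallest coordinate); probes outside regions are all
   kept. Missing probes count as p = 1 (logged).
3. **Thresholded scores** — S_t = Σ_{p_j ≤ t} effect_j · m̃_j over kept
   probes, per-probe standardized methylation, at the fixed ladder
   t ∈ {0.5, 5e-2, 5e-3, 5e-4, 5e-5, 5e-6}; each column is z-scored.
4. **PC1 summary** — the first principal component of the column-
   standardized score matrix (plain SVD), sign-oriented to correlate
   positively with the column mean, is the PMS. This avoids optimizing the
   threshold on the target.
5. **Evaluation** — logistic regression of status on the standardized PMS
   (covariates optional, off by default). Nagelkerke
   R² = [1 − exp((2/n)(ℓ₀ − ℓ₁))]/[1 − exp((2/n)ℓ₀)]; AIC = 2k − 2ℓ₁;
   BIC = k·ln n − 2ℓ₁, where k counts every supplied parameter (redundant
   columns are dropped for estimation only, so a constant covariate changes
   AIC by exactly its penalty). Perfect separation raises, never silently
   estimates. Competing scores are compared by a Vuong-type statistic on
   per-observation log-likelihood differences, z = √n·mean(d)/sd(d); the
   source does not name its non-nested test, so this standard choice is
   ours.

**Training statistics: fixed-effect by default.** When the training table
is a meta-analysis, `PolymethylationScore` prunes and weights by the
fixed-effect columns (`effect_fe`/`p_fe`), not the random-effects ones.
Rationale: when effects are sex-differential, between-stratum variance in a
sex-stratified training meta is *expected*; the DerSimonian–Laird τ²
penalty then widens the SEs of precisely the probes a stratified training
set exists to contribute (measured on synthetic cohorts with female effects
4× male: median τ² ≈ 1.3 at causal probes versus 0 in the adjusted meta,
and the stratified-trained score lost to the adjusted-trained one in 11/12
replicates under random-effects thresholding). `stat="random"` restores
the random-effects columns.

## Power simulation

One replicate draws 400 individuals (50% male) with 10,000 standard-normal
"methylation" measurements; 100 CpGs, the same set in both sexes, receive
effect sizes drawn per sex from N(mean, (mean/2)²). The male mean is 0.1;
the female mean is 0.1/0.2/0.4/0.8 across scenarios A–D. The phenotype is
Σβ_j(sex)·m_j + ε. The effect-size SD (unstated in the source design) is
half the mean so nearly all draws share the mean's sign.

**Noise calibration is within sex.** ε is drawn per sex with variance
(f/(1−f))·Var(genetic component of that sex), f = 0.5, so non-methylation
factors explain 50% of each sex's — and hence of the total — phenotypic
variance. This choice is load-bearing. Under a pooled calibration the
larger-effect sex also carries proportionally more genetic background
variance; inverse-variance weights then *suppress* that sex and the
stratified meta-analysis comes out worse than the adjusted regression —
the opposite of the behaviour this simulation exists to demonstrate. With
per-sex calibration the per-CpG standardized effect is equal across sexes
by construction, the stratified arm's power is scenario-invariant, and the
adjusted arm deteriorates as the sexes' phenotype scales diverge: the
power gap grows monotonically A→D. With zero causal CpGs the noise SD is
set to 1 so the phenotype is pure noise.

The two arms: *adjusted* regresses the phenotype on each CpG with sex as a
covariate; *stratified* standardizes the phenotype within each sex,
regresses per sex, and pools the two estimates by fixed-effect
inverse variance. The within-stratum standardization puts the per-sex
estimates on a common scale; without it the lower-variance stratum would
dominate the weights regardless of where the signal lives. Both arms use
the Frisch–Waugh residualization so 10,000 CpGs are one vectorized pass.

"Power" is operationalized as the fraction of causal CpGs below
α = 5e-6 (a Bonferroni-style 0.05/10,000); the source reports only QQ-plot
deviations, so this metric is this package's choice, and at these study
conditions absolute genome-wide power is small (per-CpG R² ≈ 0.4%, so
~0.2 expected detections per replicate): the gap ordering is crisp at
moderate thresholds (e.g. α = 1e-3) and floor-dominated at 5e-6. QQ output
is tabular (expected vs observed −log10 p), never an image.

Type-I error on null CpGs is calibrated within [0.045, 0.055] at α = 0.05
for both arms (pooled over 25 replicates × 9,900 nulls), and the stratified
arm is never materially anticonservative (λ_strat ≤ λ_adj + 0.05).

## Synthetic cohorts

`simulate_cohort` builds beta values on the logit scale: per-probe baseline
means Uniform(−1.5, 1.5); a block-correlated Gaussian field (blocks of 5
consecutive probes sharing a factor, within-block correlation `block_rho`,
default 0.4; co-methylation fixtures use 0.7 since R² must exceed 0.3
pairwise); optional covariate shifts (confounding); and case-only
status×sex effects at causal probes, converted from the ×100 beta scale to
logit shifts through the local logistic derivative so the induced
case-control beta difference matches the nominal effect to first order.
The inverse logit guarantees values in (0, 1). Probes sit every
`probe_spacing_bp` (default 300 bp) on one synthetic chromosome. Sample
sheets carry deterministic sex counts (round(frac·n)), age and smoking
distributions matching the pooled cohort profile of the study design
(cases ≈ 41.6 ± 14.2 y vs 36.7 ± 12.4 y; smoking 4.0 ± 7.8 vs −1.4 ± 5.5),
Dirichlet cell proportions around typical whole-blood composition (summing
to 1 within 1e-9), and two batches. All randomness flows from the single
config seed through one generator; same seed ⇒ bit-identical output.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: array-specific probe chemistry and normalization
artifacts, genome-realistic probe spacing and CpG-island structure,
sex-differential methylation *variance* or covariate structure, population
stratification, and batch×probe interactions. The last two absences are
why the package's synthetic experiments reproduce the simulated power
ordering but show the stratified-trained and adjusted-trained
polymethylation scores as near-equivalent on a mixed-sex target: with
effect size as the only sex asymmetry, the sexes' average effect — what a
mixed-target score needs — is estimated equally well by both designs.

## Numerical conventions

* p-values are clipped to [tiny, 1] before logs/serialization and written
  in scientific notation with six significant digits.
* Rank deficiency raises an error naming the collinear columns (QR
  diagnostic); strata with fewer than 3 samples per status group raise.
* Stouffer transforms clip p at 1e-300; z at that bound is finite (~37).
* Coordinates: 1-based inclusive everywhere except the BED writer.
* Monte-Carlo problem sizes in tests were chosen to make each check's
  statistic well-resolved at its tolerance: 50,000 statistics for mixture
  recovery, 10,000 probes × 20 replicates for family-wise calibration,
  25 seeds × 4 scenarios at 400×10,000 for the power study, 100 replicates
  for parameter-recovery coverage; the noise-calibration check runs at
  2,000 CpGs per replicate since the calibration is size-free.

## Known limitations

* The bias/inflation EM is a point estimate; no posterior uncertainty on
  (bias, inflation) is propagated into corrected SEs.
* The region caller's smoothing recruits any probe within 750 bp of strong
  signal into the called region; region boundaries are therefore
  resolution-limited by probe density.
* Co-methylation regions use adjacent-pair correlations only; long-range
  or interleaved dependence is not modelled.
* The Vuong comparison assumes non-nested competitors on identical
  samples; it is not corrected for estimated parameters.
* The power simulation's within-sex noise calibration and within-stratum
  phenotype standardization are the package's resolution of an
  underdetermined published design; both are documented above because the
  qualitative conclusion depends on them.
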