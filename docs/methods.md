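# Methods

`mrmediate` implements summary-statistics Mendelian randomization (MR) with a
two-step mediation layer, aimed at questions of the form *does an exposure
(e.g. a gut-microbiota taxon) affect an outcome (e.g. sepsis) partly through a
mediator (e.g. a plasma metabolite)?* This note records the models, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical decisions a maintainer would want to know.

## The causal model and its estimators

Each genetic variant j contributes a per-allele association with the exposure
(b_xj, SE s_xj) and with the outcome (b_yj, s_yj), estimated in two
non-overlapping GWAS cohorts. Under the instrumental-variable assumptions the
per-SNP Wald ratio θ_j = b_yj / b_xj estimates the causal effect β, with
first-order SE s_yj / |b_xj|. The battery combines the ratios:

- **IVW** — precision-weighted mean of θ_j with weights w_j = b_xj² / s_yj²,
  algebraically the WLS slope of b_y on b_x through the origin. Fixed-effects
  SE is 1/√Σw_j; the random-effects variant inflates it multiplicatively by
  √(max(1, Q/(k−1))) where Q is Cochran's heterogeneity statistic. The
  `auto` mode applies random effects when the Q p-value is below 0.05,
  fixed effects otherwise.
- **MR-Egger** — WLS of b_y on b_x *with* an intercept (weights 1/s_yj²),
  after orienting every instrument to b_xj ≥ 0. The slope is the
  pleiotropy-adjusted effect (t test, k−2 df); the intercept estimates the
  average directional pleiotropy. The intercept SE uses the plain WLS
  residual variance (multiplicative overdispersion, not floored at 1):
  flooring makes the intercept test conservative (measured type-I error
  0.005–0.03 vs 0.03–0.05 unfloored at nominal 0.05) and is a convention of
  one reference toolchain rather than part of the method.
- **Maximum likelihood** — profile likelihood of the bivariate-normal model
  b_xj ~ N(ξ_j, s_xj²), b_yj ~ N(βξ_j, s_yj²); profiling the ξ_j gives the
  one-dimensional objective ½Σ[(b_yj − βb_xj)²/(s_yj² + β²s_xj²) +
  log(s_yj² + β²s_xj²)], minimized by bounded Brent around the IVW start; SE
  from the numerical observed information. When all s_xj → 0 this reduces to
  fixed-effects IVW (tested).
- **Simple/weighted median** — (weighted) median of θ_j, weights w_j
  normalized, interpolated at cumulative weight 0.5 using midpoint cumulative
  weights. SE by seeded parametric bootstrap (default 1,000 draws of
  θ_j ~ N(θ_j, se_θj)).
- **Simple/weighted mode** — peak of the (weighted) normal-kernel density of
  θ_j on a 512-point grid, bandwidth = modified Silverman rule
  0.9·min(sd, IQR/1.349)·k^(−1/5) times a user factor (default 1); seeded
  bootstrap SE.

Binary outcomes are analyzed on the log-odds scale; every estimate is
reported with OR = exp(β) and 95% CI exp(β ± 1.96·SE).

## Instrument selection

The selection pipeline mirrors microbiome/metabolite MR practice, where few
taxa reach genome-wide significance:

1. exposure association p < 1e-5 (suggestive threshold);
2. greedy LD pruning, r² < 0.1 within 500 kb, visiting SNPs in ascending
   p-value order (ties broken by SNP id, making the output order-invariant);
3. allele harmonization against the outcome (see below);
4. exclusion of SNPs directly associated with the outcome (p < 1e-5);
5. weak-instrument exclusion F < 10, with per-SNP
   R² = 2·MAF·(1−MAF)·β² and F = R²·(n−k−1)/(k·(1−R²)), k being the current
   instrument-set size; metrics are recomputed once after removal (no
   fixed-point iteration — bounded, reproducible behavior);
6. the exposure is analyzed only if at least 3 SNPs survive and the set
   explains total R² ≥ 0.5%.

All thresholds live in `ScreenConfig` and are overridable. Note the F
formula's k in the denominator: with many modest instruments the per-SNP F
gate binds hard, which is why the synthetic screening examples use ~8–10
SNPs per exposure rather than 50.

## Harmonization

Outcome effects are re-expressed on the exposure's effect allele: direct
match → copy; swapped alleles → sign flip plus eaf complement;
strand-complement match (attempted only after direct and swapped matching
fail) → complement then as above. Palindromic variants (A/T, C/G) carry no
strand information in their allele labels; the label-based orientation is
checked against allele frequency and flipped when the two sides of 0.5
disagree. Palindromes with exposure eaf within 0.08 of 0.5 are dropped under
the default `drop_ambiguous` policy (frequency is uninformative there);
`infer_by_frequency` aligns them anyway. Proxy variants are consumed as a
user-supplied query→proxy table (the r² ≥ 0.8 requirement is the supplier's
responsibility); no reference-panel computation happens in the package.
Records with missing eaf are retained but excluded from R²/F computation and
from palindrome inference.

## Sensitivity battery

- **Cochran's Q** on the Wald ratios (χ², k−1 df) — drives the IVW
  fixed/random switch; heterogeneity is *not* by itself a robustness failure.
- **MR-PRESSO global** — observed RSS = Σ (b_yj − β̂_(−j)·b_xj)²/s_yj² with
  leave-one-out IVW fits; the null distribution comes from seeded parametric
  simulations (b*_yj ~ N(β̂_(−j)b_xj, s_yj²), b*_xj ~ N(b_xj, s_xj²)) with
  the leave-one-out fits recomputed inside every simulated dataset;
  p = (#{RSS* ≥ RSS} + 1)/(n_sim + 1). The test is mildly conservative
  (measured type-I ≈ 0.033 at nominal 0.05), inherited from using the
  estimated fit as the simulation center.
- **MR-PRESSO outlier/distortion** — per-SNP RSS contributions against their
  simulated nulls, Bonferroni threshold 0.05/k; flagged SNPs are removed and
  the IVW refitted. The Bonferroni budget concedes a ~5% family-wise false
  flag rate, so "exactly the planted outlier and nothing else" holds in
  about 95% of runs while detection itself is essentially certain at 10·SE
  displacements. The distortion p compares the estimate shift against
  removal of 1,000 seeded random same-size subsets. Note that two outliers
  displaced in *opposite* directions largely cancel in the uncorrected IVW:
  correction then improves the average error but not every single run.
- **Steiger directionality** — compares ΣR² explained in the exposure vs the
  outcome; the arrow points away from the trait with larger explained
  variance. The p-value is a z-test on the difference of Fisher-transformed
  correlations r = √R² using the two (independent) sample sizes. For binary
  outcomes the same 2·MAF·(1−MAF)·β² expression is used on the log-odds
  scale — an approximation, flagged here rather than hidden.
- **Per-SNP Steiger specificity filter** (`steiger_filter`) — keeps
  instruments explaining more variance in the trait they instrument than in
  a specified upstream trait. This matters for the mediator→outcome leg of
  mediation: SNPs acting on the mediator through the exposure have ratio
  plim direct/β1 + β2 (not β2) and must not serve as mediator instruments.
- **Robustness gate** — robust iff IVW p < 0.05, all supplied methods agree
  in sign, and neither the Egger intercept nor the MR-PRESSO global test is
  significant (Steiger, when available, must point forward). Each clause's
  failure is reported by name.

## Two-step mediation

With β0 (total exposure→outcome), β1 (exposure→mediator) and β2
(mediator→outcome, univariable — no multivariable adjustment, each mediator
analyzed marginally):

- indirect effect = β1·β2; proportion mediated = β1·β2/β0 (undefined, not
  infinite, when β0 = 0; never clamped — sign-inconsistent decompositions
  are reported with a flag);
- SE of the product by the delta method. The default is the **exact product
  variance** √(β1²se2² + β2²se1² + se1²se2²): recomputing the 23 published
  gut-microbiota→metabolite→sepsis rows from their printed inputs reproduces
  the printed SE for 22/23 rows at 3 decimals (the one miss sits on a 0.0195
  rounding boundary), whereas the two-term first-order formula matches only
  10/23. The first-order variant is available via `delta="first_order"`.
  The printed indirect effects reproduce 23/23; three printed proportions
  differ by one unit in the third decimal (unrounded internal values
  upstream), and the tests document those rows explicitly.
- the all-three-significant gate: a mediation row is reported only when β0,
  β1 and β2 are each significant at α (strict inequality), matching the
  two-step design's admission rule.

Multiplicity in screens follows per-group Bonferroni: α divided by the
number of tests configured for the group (e.g. 0.05/20 for taxonomic orders,
0.05/850 for metabolites). Group sizes are config data, not inferred from
input counts, because the tested universe may exceed the instrumentable
exposures.

## The synthetic-data generator

`simulate_triplet` emulates the three-cohort summary-statistics design:
three mutually independent cohorts (one per GWAS), so every MR leg honors
the two-sample assumption. Genotypes are Binomial(2, MAF) with MAF uniform
on [0.05, 0.5]; optional LD comes from a Gaussian copula with exchangeable
latent correlation ρ within fixed-size blocks (the emitted LD matrix reports
the generating latent r² — block-constant ρ², zero across blocks). Phenotypes
follow the linear chain

    X = Σ a_j G_j + e_x          (unit variance)
    M = β1·X + Σ d_j G_j + Σ b_j G_j·[pleio] + e_m   (unit variance)
    Y = direct·X + β2·M + Σ c_j G_j·[pleio] + e_y     (unit variance, or
        Bernoulli through a logistic link calibrated to the case fraction)

with noise variances solved so each trait has unit variance (an error is
raised when the requested parameters over-commit the variance). Two SNP
panels are generated — one acting on X, one acting directly on M — so each
leg has its own valid instruments; without the second panel the M→Y leg is
confounded through the shared X-SNPs and no estimator can recover β2.
Summary statistics are per-SNP marginal regressions (closed-form simple
linear regression; vectorized Newton logistic fits for a binary Y) computed
separately in the three cohorts.

Defaults are a well-powered desk-scale study: 50 + 50 SNPs, total
heritability 10% per trait panel, three cohorts of 50,000, β1 = 0.4,
β2 = 0.5, direct = 0.1 (total effect 0.3, true mediated proportion 2/3), no
pleiotropy, independent SNPs. Pleiotropy is planted on a configurable
fraction of exposure SNPs: balanced effects are N(0, sd) (InSIDE-satisfying);
directional effects have nonzero mean and are sign-aligned with the
exposure-increasing allele — with arbitrary allele coding the planted
direction would cancel under Egger's instrument reorientation and
"directional" would be meaningless. All randomness flows from a single seed
through named SeedSequence substreams (per cohort and stage), so identical
truth + seed reproduce identical tables bit for bit.

What the generator does **not** emulate: realistic microbiome effect-size
spectra or metabolite pathway structure, sample overlap between cohorts,
population stratification, winner's-curse selection into the exposure GWAS,
or assortative mating. Passing tests therefore demonstrate the estimators'
behavior under the model's own assumptions, not robustness to those
real-data complications.

## Numerical choices and problem sizes

- Bootstrap SEs: 1,000 seeded draws by default (reduced in fast tests).
- MR-PRESSO: n_sim = 1,000 default; the calibration studies use n_sim = 200
  with 600 replicates, and parameter-recovery studies use 100 replicates of
  the default 50k-per-cohort chain — sizes chosen so the Monte-Carlo error
  of each reported rate is well below the width of the band being checked.
- Maximum likelihood: bounded Brent on ±10·max(1, |start|) around the IVW
  start, xatol 1e-10; non-convergence or a non-positive observed information
  yields a flagged estimate (`converged=False`), never a silent value.
- Ties in LD pruning are broken lexicographically by SNP id; output is
  sorted by (chrom, pos), making the pipeline order-invariant.
- p-values are clipped away from exact 0 to keep downstream log-scale
  consumers safe; SEs of exactly collinear Egger fits are floored at 1e-300
  to avoid division by zero.

## Known limitations

- First-order IVW inherits the classical weak-instrument attenuation of
  roughly −1/F̄ (about −1% at the default simulation's mean F ≈ 100) and its
  SE ignores exposure-side noise, understating the empirical sampling SD by
  ~6–8% under the default conditions. Jointly these put nominal-95%
  (2·SE) coverage at about 90–95% per leg in the recovery studies; a
  100-replicate batch can occasionally dip just below 90% for one leg.
  This is a property of the standard estimator, reported rather than
  patched with nonstandard SE inflation.

- β2 comes from univariable MR; multivariable MR and joint multi-mediator
  decomposition are out of scope (each mediator is marginal).
- The Steiger z-test treats the two R² values as independent correlations;
  with overlapping cohorts it would be anticonservative (the generator never
  produces overlap).
- The liability-scale R² used for binary traits is a log-odds approximation.
- LD pruning assumes the user-supplied r² matrix is on the same samples as
  the exposure GWAS; no panel computation is provided by design.
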