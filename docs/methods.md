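# Methods

This note records the statistical model behind `adipomr`, the defaults and
why they were chosen, what the synthetic cohorts do and do not emulate, and
the numerical decisions a maintainer would otherwise have to reverse-engineer.

## The generative model

Everything downstream is tested against cohorts drawn from a single
structural model (`adipomr.simulate`):

- **Genotypes.** `n_variants` independent bi-allelic variants; dosage of the
  effect allele is Binomial(2, MAF), i.e. exact Hardy–Weinberg proportions.
  Linkage disequilibrium and population stratification are deliberately not
  modelled: the emulated instrument sets are LD-pruned (r² ≤ 0.01), and with
  no stratification in the generator the genetic adjustment set carries no
  principal components. By default 670 variants are drawn, 84 of them rare
  (MAF < 1%), so the MAF filter reproduces the 586-variant instrument
  scenario.
- **Exposure.** On the standardized scale,
  `X_z = sqrt(r²)·z(G·w) + b·U + sqrt(1 − r² − b²)·ε`,
  where `U ~ N(0,1)` is a single latent confounder shared with proteins and
  hazard. The score explains `r²` of exposure variance in expectation
  (default 0.0206); the exposure is then mapped to its natural scale
  (mean 23.9, SD 3.4 BMI units) so the per-unit → per-SD rescaling logic is
  exercised rather than assumed. The confounder loading defaults to
  `b = 0.4`: strong enough that naive regression is visibly biased, which is
  the situation the triangulation exists for. True variant weights are
  positive (effect-allele coding), so the unweighted score remains a usable
  instrument.
- **Proteins.** Each of 92 panel proteins is
  `β·X_z + γ·U + (pleiotropy and shared-factor terms, off by default) + noise`,
  scaled to unit variance — the "standardized NPX" convention. Thirty
  proteins respond to the exposure (β between 0.12 and 0.50, patterned on
  the magnitudes such studies report); four of them (IL12, CSF1, DCN, CASP8)
  have a negative β with a strong positive confounder loading, so their
  observational estimate is positive while the genetic estimate is negative
  — the discordance case the report stage must flag, not smooth over. Two
  proteins (IL21, IL35) are generated ~99.5% below their limit of detection
  and must be dropped by the >99%-below-LOD rule. Below-LOD values are
  retained and flagged, mirroring assays that report them; exclusion is a
  downstream analytic decision. The covariance among proteins beyond the
  shared exposure/confounder structure is not calibrated to any particular
  dataset; an optional shared factor loading exists but defaults to zero.
- **Survival.** Event times have a Weibull baseline (exponential by default;
  the emulated analyses make no baseline-hazard assumption) with
  proportional hazards on the exposure (log HR 0.15/SD), the confounder
  (0.20), age and sex, and ten proteins with direct log HRs between −0.27
  and 0.34 (chosen to match the span of reported protein–CVD hazard
  ratios, 0.76–1.40). The baseline rate (0.020/yr) and dropout give ~23%
  cumulative incidence over 10 years, matching the ~150/628 event count of
  the emulated subcohort. Dropout is an independent exponential process
  calibrated so a fraction `censor_rate` leaves before administrative
  censoring; `censor_rate = 1` is the degenerate all-censored case.
- **Determinism.** All randomness flows from one seed through named
  substreams (variants, genotypes, confounder, …), so any stage can be
  regenerated independently of execution order and two runs of the same
  config are byte-identical.

What the generator does **not** emulate — LD, population structure, assay
batch effects, non-normal protein tails, informative censoring, competing
risks — bounds what passing tests show: estimator correctness under the
stated model, not robustness to those features of real data.

## Analysis defaults and their rationale

- **Adjustment sets.** The observational set (age, age², sex, region,
  education, income, alcohol, self-rated health, SBP, diabetes, statin,
  kidney disease, fasting time) and the genetic set (age, age², sex, region,
  education, smoking, alcohol) are named, reproducible objects; both 2SLS
  stages use the genetic set. Missing covariates are handled by
  complete-case analysis with a logged count.
- **2SLS standard errors** are the stage-2 model-based SEs, ignoring
  first-stage sampling error. With stage 1 ~120× larger than stage 2 the
  neglected variance is of order n₂/n₁ ≈ 1%; a two-stage bootstrap option
  exists for checking. A first-stage partial F below 10 triggers a warning
  rather than a refusal.
- **Multiplicity.** "5% FDR" is implemented as Benjamini–Hochberg step-up.
  The ordered-p-value ("Rényi-style") band defaults to the BH step-up line,
  so the band's surpassing set is by construction a superset of the
  BH-significant set; it is labelled approximate, as the formal band
  construction is not pinned down.
- **Harmonization.** Weight tables and summary statistics match on id +
  alleles; an effect/other swap flips the sign; palindromic variants are
  dropped when MAF > 0.42 (weights) or EAF ∈ (0.42, 0.58) (two-sample
  pairs). Variants missing from a weight table are dropped with a log
  entry — proxy lookup is out of scope.
- **Cis-window exclusion** takes BED-like spans (0-based half-open,
  converted to 1-based internally) and drops variants with distance
  ≤ window to the nearest span edge; a variant exactly window+1 bp away is
  retained.
- **Cox fits** maximize the Efron-tied partial likelihood via lifelines'
  Newton–Raphson with the convergence precision tightened to 1e-9 so that
  small-sample fits agree with direct maximization of an independently
  coded partial likelihood to well below 1e-4. Follow-up time is the time
  axis; the subcohort is a simple random sample, so unweighted Cox within
  it is appropriate (no Prentice weighting). Tests cross-check one fit
  against `survival::coxph` in R.
- **Attenuation** is reported on the log-HR scale by default (the HR
  excess scale is an explicit option, as published attenuation percentages
  rarely state their scale), refuses a percentage when the base exposure
  coefficient has |z| < 0.1, and is reported per mediator set without any
  additivity adjustment — joint and marginal attenuations are expected to
  disagree. At the emulated scale (~590 people, ~140 events) the percent
  attenuation carries large sampling noise; runs at a given seed can
  exceed 100%. That is the information content of such a subcohort, and
  the pipeline reports it as computed.
- **Meta-analysis** defaults to fixed-effect pooling with the
  DerSimonian–Laird random-effects model emitted alongside; ratio measures
  (RR/HR/OR) are pooled on the log scale after CI→SE conversion, and a
  `mixed_measures` flag marks pools that merge different effect measures
  instead of silently unifying them. Cross-checked against `metafor::rma`.
- **Colocalization** is the single-causal-variant ABF method with the
  canonical priors (p1 = p2 = 1e-4, p12 = 1e-5) and prior effect variance
  0.15² for quantitative traits (0.2² suggested for log-odds); both are
  configurable since the originating analyses rarely publish them.
- **Pipeline isolation.** A failure in one protein's model (degenerate
  trait, separation) is logged and skipped; a 90-trait panel must not die
  on one column. The manifest records the seed and SHA-256 of every table.

## Simulation scales used by the test suite

Statistical guarantees are checked at fixed seeds with problem sizes chosen
to keep the full suite within minutes while leaving the checks
well-powered: 2SLS coverage/bias at stage-1 n = 50 000, stage-2 n = 1 000,
400 replicates; Egger intercept calibration and weighted-median breakdown
at 50 variants, 500 replicates; Cox recovery at n = 4 000 with ~20%
events, 200 replicates; FDR control on 90-trait global nulls, 1 000
replicates; Steiger orientation at n = 10 000, 500 replicates; end-to-end
determinism on a 4 000-person configuration. In the weighted-median
breakdown scenario the summary-statistic outcome SE is set to 0.002 so the
check measures the estimator's breakdown property rather than
finite-sample ratio noise, which at looser precision biases any
median-type estimator upward regardless of implementation.

## Known limitations

- The Egger SE uses the conventional multiplicative residual scale bounded
  below by 1; exact agreement with packages using unbounded scales will
  differ on underdispersed data.
- The weighted-median SE is a parametric bootstrap (default 1 000 draws,
  seeded), not the analytic approximation; small n_boot gives a noisy SE
  though the point estimate is deterministic.
- `renyi_band` is a banded Q–Q summary, not a formal Rényi-statistic test.
- The case-subcohort machinery covers the simple-random-subcohort case
  only; Prentice/Barlow weighting for enriched case sets is not
  implemented.
- VCF export writes genotypes only (GT, unphased) and is meant for
  interoperability smoke tests, not as a general-purpose writer.
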