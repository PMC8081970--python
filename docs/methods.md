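# Methods

## Model and assumptions

`mrtools` implements two-sample Mendelian randomization (MR) on summary
statistics. A genetic variant is a valid instrument for an exposure if it
is (i) robustly associated with the exposure, (ii) independent of
confounders of the exposure–outcome relationship, and (iii) affects the
outcome only through the exposure. Under these assumptions, for instrument
*k* with exposure association *X_k* (SE σ_Xk) and outcome association
*Y_k* (SE σ_Yk), the Wald ratio *Y_k*/*X_k* estimates the causal effect of
one SD of exposure on the outcome log-odds.

The pooled fixed-effect inverse-variance-weighted (IVW) estimate is

    β̂ = Σ X_k Y_k σ_Yk⁻² / Σ X_k² σ_Yk⁻²
    σ̂ = (Σ X_k² σ_Yk⁻²)^(−1/2)

equivalently, precision-weighting the Wald ratios by 1/se_k², or an
origin-constrained weighted least-squares regression of Y on X with
weights σ_Yk⁻² (the test suite cross-checks this identity numerically
against statsmodels WLS). Note the SE is the inverse *square root* of the
summed weights; the plain reciprocal sometimes seen in print units-checks
wrong (it is the variance) and reproduces no published interval.

Heterogeneity is Cochran's Q = Σ w_k (ratio_k − β̂)² with w_k = 1/se_k²,
χ² with k−1 df under homogeneity. Two pooled variants are reported for
k ≥ 2:

- `ivw_fixed` — the formula above (the documented default);
- `ivw_scaled` — the same β̂ with SE inflated by max(1, √(Q/df)). This is
  the behaviour of weighted regression with residual variance floored at
  one, the default of widely used MR software, and it matters exactly when
  instruments disagree more than their SEs allow (Q/df > 1). With Q/df ≤ 1
  the two coincide.

ORs and CIs are exp-transformed normal intervals; p-values are two-sided
normal (chi-square for Q). Multiple-exposure runs flag significance at
α/family (Bonferroni), with the family defaulting to the number of
exposures analyzed.

## Pipeline thresholds (defaults)

| parameter | default | meaning |
|---|---|---|
| `p_threshold` | 5×10⁻⁸ | genome-wide significance filter (strict <) |
| `clump_r2` | 0.01 | removal threshold: r² **above** this prunes a neighbour |
| `clump_window` | 1,000,000 bp | ±window around the index SNP (2 Mb span) |
| `proxy_r2` | 0.8 | minimum LD for proxy substitution (strict >) |
| `maf_ambiguity_threshold` | 0.45 | palindromic drop rule on exposure-side MAF (strict >) |
| `eaf_tolerance` | 0.2 | accepted EAF disagreement after palindrome orientation |
| `alpha`, family | 0.05, n exposures | Bonferroni significance |
| `ci_level` | 0.95 | confidence level |

Design choices where conventions genuinely differ:

- **Window semantics.** "Within 1 Mb" is read as ±1 Mb from the index SNP
  (inclusive at the boundary), the common clumping semantics.
- **Clumping tie-break.** Equal p-values are broken by lexicographic
  variant id, making output invariant to input order; an exhaustive
  reference implementation is kept in the tests as an oracle.
- **Whose MAF for the palindrome rule.** The exposure side: instruments
  are defined on the exposure panel. The outcome EAF is used only to infer
  orientation (same side of 0.5 → unchanged; opposite → sign flip);
  disagreement beyond `eaf_tolerance` after alignment warns rather than
  errors, since the drop rule already removed the genuinely ambiguous
  range.
- **Missing other allele.** Published tables sometimes omit the non-effect
  allele (the packaged table does). Such records harmonize on
  effect-allele equality alone with a warning; palindrome status is then
  unknowable, so no palindromic drop can fire. Indels and multi-allelic
  sites are rejected outright.
- **Proxy substitution.** Aligning a proxy's sign against the *target's*
  alleles would require phase (signed D'), which r² does not carry. The
  pipeline therefore substitutes the proxy variant on both sides (its own
  exposure record, its own alleles), and requires it to share the target's
  chromosome and clumping window when the LD matrix carries that
  information. Targets without a usable proxy are logged and excluded.
- **k = 1 reduction.** Single-instrument IVW short-circuits to the Wald
  ratio so the equality is exact in floating point, and is labelled
  `wald_single` by the model's auto method.

## Packaged instrument table

The shipped table (`mrtools/data/il_ms_instruments.tsv`, loaded by
`load_table1_fixture`) holds nine instruments for six circulating
interleukins with their multiple sclerosis associations (14,802 cases /
26,703 controls, European ancestry), exactly as published: betas and SEs
to two decimals, p-values in publisher notation (normalized on ingest),
no non-effect alleles, no positions. Two consequences are worth knowing:

- Recomputed ORs can differ from the originally published ones by up to
  about ±0.02, purely from two-decimal input rounding. The packaged-table
  recomputations give sIL-2Rα 1.21 (published 1.22), IL-1Ra 0.93 (0.94),
  IL-16 0.96 (0.96), IL-6 single-SNP 0.88 (0.87), IL-18 0.84 (0.85).
- The same rounding moves the IL-1Ra IVW p-value from the published 0.027
  to 0.055 — across the nominal 0.05 line. The qualitative conclusion
  (suggestive, not Bonferroni-significant) is unchanged, but the
  "p < 0.05" reading is not reproducible from two-decimal inputs.
- The published pooled two-SNP IL-6 estimate (OR 1.00) implies an allele
  coding for rs643434 that the printed table cannot resolve (the raw-table
  Wald ratio has the opposite sign). The pipeline reports the raw-table
  pooled value (0.89) and the single-SNP IL6R estimate; the two-SNP IL-6
  pooled OR is not treated as reproducible.
- The published IL-16 upper CI (2.12) is inconsistent with its own OR and
  SE and is treated as a typo; intervals are recomputed.

## Synthetic-data generator

`SyntheticScenario`/`simulate_two_sample` emulate paired summary
statistics directly on the summary scale: per variant, a MAF is drawn
uniformly from `maf_range`, a true per-SD exposure effect x* from
`exposure_betas`, and the observed beta is x* plus normal noise with
SE = 1/√(2p(1−p)N) — the standard approximation for a standardized
(or log-odds) per-allele regression coefficient. The true outcome effect
is `causal_effect`·x* plus a normal pleiotropy draw (SD
`pleiotropy_sd`); the outcome side uses its own sample size. Observed
EAFs get binomial sampling noise, alleles are assigned with the requested
palindromic fraction, and each outcome record is independently re-coded
to the opposite allele with probability ½ so harmonization is exercised
end to end. All draws come from one `numpy.random.default_rng` (PCG64)
seeded by `scenario.seed`; identical seeds give identical records on any
platform.

Default scenario (5 variants, exposure betas 0.1–0.6 SD, MAF 0.1–0.5,
N = 50,000 per sample, palindromic fraction 0.2, no pleiotropy) mirrors
the application: per-SD instrument effects between 0.08 and 0.73 with
GWAS of tens of thousands of samples.

What the generator does *not* emulate: individual-level genotypes,
case-control ascertainment (effects are simulated directly on the
log-odds scale with normal noise), sample overlap between the two GWAS,
population stratification, and LD-induced correlation of *effect
estimates* (LD blocks shape the r² matrix used for clumping, not the
noise covariance). Calibration results on synthetic data therefore speak
to the estimator's arithmetic and the harmonization logic, not to those
real-data pathologies.

`recovery_study` runs simulate → harmonize → fit per replicate
(per-replicate seeds spawned from the scenario seed) and reports bias,
empirical SE, CI coverage and rejection rate. At desk scale the suite
checks: type-I error 0.05 ± 0.02 at 1,000 null replicates; under a causal
effect of 0.19, mean recovery within 3 Monte-Carlo SEs and coverage in
[0.92, 0.98] at 500 replicates; weak-instrument bias (the Wald SE ignores
σ_Xk) decreasing from N = 1,500 to N = 60,000. Replicate counts were
chosen to keep Monte-Carlo error well below the tested margins while the
whole suite runs in seconds.

## Numerical and degenerate-input conventions

- Strict inequalities throughout (p < threshold, r² > threshold,
  MAF > 0.45), so boundary values are kept/excluded deterministically.
- x = 0 makes the Wald ratio undefined → error; empty estimate sets,
  k < 2 for Q or scaling → error.
- p-values written by the generator are floored at the smallest positive
  double; the record-level p/z consistency check (factor of two on the
  normal-quantile scale, warn-only) skips p ≤ 1e-300 where double
  precision saturates.
- Human-readable output rounds OR/CI to two decimals; machine output
  (`results.tsv` etc.) carries 10 significant digits and round-trips.

## Known limitations

Only Wald-ratio and IVW estimation are provided — no MR-Egger, median or
mode estimators, no Steiger filtering, no multivariable MR — so pleiotropy
appears only as heterogeneity (Q, scaled SEs), not as a corrected
estimate. The first-order Wald SE understates uncertainty for weak
instruments. Proxy handling requires the proxy to be present in both data
sets. LD matrices are consumed, never computed from genotype panels.
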