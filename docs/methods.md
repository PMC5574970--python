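# Methods

## Statistical model

Two-sample summary-data Mendelian randomization treats each SNP *i* as an
instrumental variable. Writing γᵢ for the true per-allele effect on the
exposure (years of age at menarche) and Γᵢ for the true per-allele effect on
the outcome (SD units of time in education), a valid instrument satisfies
Γᵢ = β γᵢ under an additive, interaction-free model, where β is the causal
effect (SD per year). The observed summary statistics are
bxᵢ ~ N(γᵢ, sxᵢ²) and byᵢ ~ N(Γᵢ, syᵢ²), independent across the two
samples (non-overlapping consortia), with sxᵢ, syᵢ treated as known.
Violations of the exclusion restriction are modelled as
Γᵢ = β γᵢ + αᵢ with αᵢ the direct (pleiotropic) effect.

### Estimators

- **Wald ratio**: β̂ᵢ = byᵢ/bxᵢ. Delta-method SE, second order by default,
  se² = syᵢ²/bxᵢ² + byᵢ²·sxᵢ²/bxᵢ⁴; the first-order form syᵢ/|bxᵢ| is kept
  because it makes IVW algebraically identical to a zero-intercept weighted
  least-squares fit of by on bx with weights 1/sy² (used as an oracle
  cross-check). The exposure–outcome sampling covariance is fixed at zero
  (two-sample design).
- **Fixed-effect IVW**: β̂ = Σwᵢβ̂ᵢ/Σwᵢ, wᵢ = se(β̂ᵢ)⁻², se(β̂) = (Σwᵢ)^(−½),
  two-sided normal p-values, CI multiplier 1.959964 (the exact 97.5% normal
  quantile, not 1.96).
- **Heterogeneity**: Cochran's Q = Σwᵢ(β̂ᵢ − β̂)², df = n − 1;
  I² = max(0, 100·(Q − df)/Q), with the Higgins–Thompson test-based CI on
  H = √(Q/df): a normal interval for ln H using
  se(ln H) = (ln Q − ln df)/(2(√(2Q) − √(2df−1))) when Q > df and the
  small-Q closed form otherwise, back-transformed and truncated to
  [0, 100]. At the motivating study's geometry (df = 121, I² = 48%) this
  method reproduces the published interval (36%, 58%) to the printed digit.
  Heterogeneity is declared present above I² = 25% and read as a proxy for
  pleiotropy. With a single instrument the heterogeneity block is absent
  rather than zero — no diagnostics are fabricated.
- **MR-Egger**: weighted linear regression by = α + β·bx (weights 1/sy²)
  after re-orienting all instruments to bx ≥ 0 (the fit is
  orientation-dependent; the exposure-increasing-allele convention is
  enforced package-wide). Standard errors use a multiplicative residual
  scale floored at 1 — overdispersion inflates the SEs, underdispersion is
  never credited — and inference uses t(n−2) quantiles, the convention of
  the Egger-regression literature. I²_GX, the inverse-variance-weighted
  heterogeneity of the bx values, quantifies regression dilution: values
  near 100% mean exposure-side measurement error is negligible relative to
  the spread of instrument strengths.
- **Weighted median**: order the β̂ᵢ, accumulate normalized weights
  wᵢ/Σwᵢ at the midpoints cumsum(w) − w/2, and interpolate linearly at
  cumulative weight 0.5 (with equal weights this is exactly the ordinary
  interpolated median; ties are broken by a stable sort on snp_id).
  Uncertainty by parametric bootstrap: bx*ᵢ ~ N(bxᵢ, sxᵢ),
  by*ᵢ ~ N(byᵢ, syᵢ), re-deriving ratios *and weights* each iteration;
  default 10,000 iterations, seed always recorded. The default CI is the
  normal approximation estimate ± 1.959964·SE (published median CIs are
  symmetric); a bootstrap-percentile CI is available
  (`ci_method="percentile"`).
- **Unweighted allele score**: fixed-effect IVW pooling of the byᵢ
  themselves (weights 1/syᵢ²) on the exposure-increasing orientation. Used
  strictly as an association test (its magnitude is not a causal effect per
  year); it avoids winner's-curse bias because discovery-stage exposure
  effect sizes never enter. The **negative control** runs the same score in
  a population without the exposure; the comparison passes when the exposed
  population is significant at α = 0.05 and the control is not.
- **Unit conversion**: an effect of β SD of time in education equals
  β·3.6 years (the outcome GWAS's reported SD) = β·3.6·365.25 days; days
  are rounded to integers for display only.

## Harmonization

The outcome table is aligned onto the exposure's effect alleles by direct
match, allele swap (sign flip, eaf → 1 − eaf), strand complement, or
complement-plus-swap; irreconcilable pairs are excluded with reason
`allele_mismatch`. Palindromic variants (A/T, C/G) cannot be resolved from
labels; the default policy aligns them by effect-allele frequency and drops
them when either frequency is missing or lies in (0.42, 0.58) — the
conservative community convention; `drop` and `keep_as_is` are available.
Finally each instrument is re-oriented so bx ≥ 0. Every SNP in either input
appears exactly once in the harmonization report (kept with its action, or
excluded with a reason code, including `missing_in_outcome` /
`missing_in_exposure`); nothing is dropped silently. Proxy/LD lookup is out
of scope — a SNP missing from one source is excluded, not substituted.
Missing eaf is tolerated except where a computation needs it (palindromic
alignment, MAF-corrected funnel coordinates), in which case only the
affected SNP is omitted from the affected computation.

## Synthetic-data generator

Per SNP: maf ~ U(maf_range); γᵢ = |N(0, gamma_sd)|; αᵢ per pleiotropy model
(`none`; `balanced`: N(0, sd); `directional`: N(mean ≠ 0, sd), independent
of γ so InSIDE holds; `inside_violating`: αᵢ correlated 0.8 with γᵢ),
applied to a random `invalid_prop` fraction of SNPs; Γᵢ = β·γᵢ + αᵢ;
sxᵢ = (2·n_exposure·maf(1−maf))^(−½) on a unit-variance trait scale and
analogously syᵢ; observed effects drawn independently (two-sample).
`selection_p` retains only SNPs whose observed exposure association passes
the threshold, reproducing winner's curse in the selected bx. All
randomness flows from one `numpy` Generator seeded by the truth record; the
same truth gives byte-identical output files. Allele pairs are drawn from
non-palindromic combinations so that harmonization of synthetic data is
exact by construction; `scramble_alleles` then randomizes labels/strands in
the outcome table to exercise the harmonizer.

**Defaults are the motivating study's geometry**: 122 instruments,
n_exposure = 182,416, n_outcome = 118,443 (women; the male control uses
147,474), β = 0.045 SD/year, maf ∈ (0.1, 0.5), balanced pleiotropy.
gamma_sd = 0.045 years/allele puts the median instrument F near 60 (the
study's F values span 25–576); pleiotropy_sd = 0.0055 SD/allele was
calibrated by simulation so the median I²_MR across seeds lands near the
study's 48% (per-seed spread roughly 25–55%) — the first-order analytic
value (0.0044 from E[Q] ≈ df + pleio_sd²·Σsy⁻²) undershoots because the
second-order ratio weights absorb part of the pleiotropic variation. The
preset is a calibration to these two observable targets, not a claim about
the real genetic architecture.

What the generator does **not** emulate: LD between instruments (all SNPs
independent), population stratification, secular birth-year trends, sample
overlap, binary/ordinal outcome coarsening, and significance selection is
off by default (the preset emulates a published post-selection instrument
list only through its effect-size scale, so a weak-F tail remains —
instruments with F < 10 are flagged, never removed). Passing tests on this
generator therefore validates the estimators' statistical behaviour, not
robustness to those real-data features.

## Numerical choices and degenerate inputs

- bx = 0 makes the Wald ratio undefined → error, never silently skipped.
- Q requires ≥ 2 estimates, MR-Egger and the weighted median ≥ 3; all bx
  equal makes the Egger slope unidentifiable → error.
- I² CI is undefined at df = 1 with Q ≤ df (NaN); I² point at Q = 0 is 0.
- Bootstrap draws that hit bx* = 0 exactly are nudged to the smallest
  positive float; below 1000 iterations a warning is emitted and the run
  proceeds.
- The second-order Delta SE carries O((sx/bx)²) truncation error — about
  3(sx/bx)² in relative terms, i.e. ~3% at instrument z = 8 and < 2% only
  for z ≳ 10. The Monte-Carlo validation of the formula therefore samples
  instruments with z ∈ [10, 24]; for weaker instruments the reported SE is
  a mild underestimate of the true ratio sampling SD (whose raw moments do
  not even exist), which is the standard and accepted behaviour of
  Delta-method ratio SEs.
- Under an unselected half-normal effect-size distribution the near-zero-γ
  tail makes per-SNP ratios heavy-tailed and drags E[Q] below df; the
  Q ~ χ²(df) calibration check is therefore run on significance-selected
  instruments (p < 5×10⁻⁸), which is also how real instrument lists arise.

## Design choices

- Estimators follow the scikit-learn fit/predict protocol (X = bx, y = by,
  SEs as fit keywords, fitted attributes with trailing underscores) so they
  compose with sklearn tooling; thin functions wrap them for
  table-in/table-out use.
- MR-Egger regression is delegated to `statsmodels` WLS (with the scale
  floor applied on top); all closed-form estimators are implemented
  directly.
- The weighted-median breakdown property is asymptotic in per-SNP ratio
  precision: under one-sided contamination far from the truth the
  population weighted median sits ≈ Φ⁻¹(0.5/(1−ρ)) ratio-SEs above β for
  invalid-weight fraction ρ. Its recovery test therefore simulates large
  GWAS (4×10⁶ per sample, β = 0.2, 40% invalid weight) so the predicted
  displacement (≈ 1.5% of β) is well inside the 5% criterion; at the
  motivating study's sample sizes the same contamination would displace the
  median by more than 5% — a property of the estimator, not of this
  implementation.
- Funnel-plot asymmetry is reported numerically (precision-weighted sign
  score of β̂ᵢ − β̂_IVW, plus the Egger intercept p-value) rather than by
  visual inspection; the "MAF-corrected" funnel x-coordinate is implemented
  as bx·√(2·maf(1−maf)) (per-allele → per-genotype-SD standardization) and
  flagged as an interpretation, since the source figure does not define it.
- Replicate counts used by the validation suite: 1000 replicates for IVW
  coverage/bias and the Egger/median recovery checks, 2000 for the Egger
  intercept type-I error and the Q calibration, 10⁶ draws per instrument
  for the Delta-method Monte-Carlo; smaller spot-check versions (300–600
  replicates) run inside the unit-test modules.

## Known limitations

- No random-effects or over-dispersed IVW, mode-based estimators,
  MR-PRESSO/outlier removal, leave-one-out, Steiger filtering, or
  multivariable MR.
- No LD-aware operations: clumping, proxy search and reference-panel
  lookups are out of scope; instruments are assumed independent.
- The allele-score "test" exit of the negative control is a binary
  pass/fail at α = 0.05; a non-significant control in an under-powered
  sample is weak evidence, and the run only warns (exit code 2), it does
  not fail.
- Exact reproduction of a published weighted-median CI is stochastic: the
  bootstrap iteration count and seed behind any published interval are
  generally unreported, so only the point estimate is deterministic.
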