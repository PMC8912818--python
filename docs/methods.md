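# Methods

This note documents the statistical procedures implemented in `mrscreen`,
the conventions adopted where the field has more than one, and what the
synthetic-data experiments do and do not establish.

## Data model and harmonization

All computation runs on per-SNP summary associations (identifier, effect
and other allele, effect-allele frequency, beta, SE, p, N). Exposure betas
are interpreted per SD of the exposure; outcome betas as log-odds.
Coordinates are purely identifier-based (rsID); no genome builds or
positions are modeled, because published instrument lists for this kind of
screen are rsID-level.

Harmonization aligns each outcome record to the exposure's effect allele:
label match, label swap (sign flip, EAF → 1−EAF), or strand complement
when unambiguous. Palindromic SNPs (A/T, C/G) cannot be strand-resolved
from labels; the default `infer` policy orients them by allele frequency
and requires both EAFs outside [0.42, 0.58] — inside that band, or with
either EAF missing, the SNP is dropped. A `drop` policy discards all
palindromic SNPs for users who prefer the stricter convention; the choice
is exposed because either is defensible and published screens rarely state
which their tooling applied. Duplicate rsIDs in an input keep the
smallest-p row (a deterministic rule; inputs of this kind occasionally
concatenate sources).

Proxy substitution accepts a user-supplied SNP → (proxy, r²) map and
substitutes only when r² > 0.8 and the proxy exists in the outcome table;
instruments with no admissible proxy are removed. Because the map carries
no exposure-side association for the proxy, the original SNP's exposure
record is carried over under the proxy's identifier — at r² > 0.8 the two
signals are nearly interchangeable, and the substitution count is logged so
the approximation is auditable.

## Instrument selection and strength

Defaults: genome-wide threshold p < 5×10⁻⁸ with a suggestive fallback
p < 1×10⁻⁵ (applied only when no genome-wide hit exists, and flagged in the
report), MAF ≥ 0.01, greedy LD clumping at r² ≤ 0.01. The clumping window
(5000 kb) is retained as metadata only: independence is decided entirely by
the supplied pairwise r² lookup, since positional windowing cannot be
reproduced without a reference panel. Rows with missing EAF pass the MAF
filter (unknown frequency is not evidence of rarity).

Per-SNP variance explained is R² = 2β²·EAF·(1−EAF)/SD², with SD defaulting
to 1 (SD-unit exposures) and overridable per exposure; F = R²(N−2)/(1−R²).
The study table reports the sum of R² and the mean F over instruments.
When a SNP has no usable N, its F is reported missing rather than zero.

## Estimators

- **IVW**: β̂ = Σwγ̂Γ̂ / Σwγ̂², w = 1/σ_y². Fixed-effect
  SE = (Σwγ̂²)^(−1/2). The multiplicative random-effects model — the
  primary analysis — multiplies it by √φ with φ = max(1, Q/(J−1)); the
  floor at 1 prevents anti-conservative SEs when instruments under-disperse.
  p-values use the normal reference.
- **MR–Egger**: two-parameter weighted regression, same weights.
  Instruments are first oriented so every γ̂ ≥ 0 (flipping γ̂ and Γ̂
  together), because the fit is not invariant to allele orientation and
  this is the standard convention. Coefficient SEs use a multiplicative
  dispersion floored at 1; p-values and CIs use t with J−2 df (the CI
  quantile follows the same reference as the p-value).
- **Medians**: Wald ratios sorted ascending; the simple median uses
  midpoint interpolation for even J; the weighted median takes the value at
  cumulative weight 0.5 with linear interpolation between bracketing order
  statistics, weights γ̂²/σ_y² (inverse first-order ratio variance; a
  `second_order` switch adds the γ̂-noise term for users who prefer it).
  SEs are the SD of the estimator over n_boot = 1000 parametric bootstrap
  replicates, γ̂* ~ N(γ̂, σ_x), Γ̂* ~ N(Γ̂, σ_y), deterministic given the
  seed. Note that with the interpolation definition, duplicating every
  instrument reproduces the estimate only approximately (the interpolation
  nodes shift by O(wⱼ)); the discrepancy vanishes as J grows.
- Wald-ratio SE is first-order (σ_y/|γ̂|); accurate when instruments are
  strong and the outcome side dominates the noise, which instrument
  selection enforces in practice.

Applicability: IVW needs J ≥ 2; Egger, medians and leave-one-out need
J ≥ 3; the outlier framework needs J ≥ 4 (its leave-one-out slope plus a
residual needs three remaining SNPs). The pipeline reports methods below
their threshold as not-applicable rather than failing.

## Diagnostics

**Cochran's Q** = Σ wⱼ(β̂ⱼ − β̂)² over Wald ratios with wⱼ = γ̂ⱼ²/σ_yⱼ²,
evaluated at the fixed-effect IVW estimate (its minimizer), referred to
chi-square with J−1 df.

**Outlier framework (MR-PRESSO style).** Observed statistic
RSS = Σⱼ wⱼ(Γ̂ⱼ − β̂₍₋ⱼ₎γ̂ⱼ)² with β̂₍₋ⱼ₎ the leave-one-out fixed-effect
IVW slope and wⱼ = 1/σ_yⱼ². The null distribution is built from n_sim
parametric replicates (Γ*ⱼ ~ N(β̂₍₋ⱼ₎γ̂ⱼ, σ_yⱼ), γ*ⱼ ~ N(γ̂ⱼ, σ_xⱼ)) on
which the same statistic — including the leave-one-out slopes — is
recomputed, fully vectorized. The global p is the exceedance fraction,
censored at 1/n_sim and displayed "<1/n_sim" at zero exceedances; n_sim
defaults to 5000, so the finest reportable p is 2×10⁻⁴. Per-SNP outlier
p-values compare each observed weighted squared residual with its simulated
distribution and are Bonferroni-multiplied by J; flagged SNPs trigger an
outlier-corrected IVW and a distortion test of the raw-vs-corrected
difference against 1000 random removals of the same number of SNPs.
Because screening tables often print a single "P-outlier" per exposure and
the convention is ambiguous, the result carries both candidates, labeled:
the minimum adjusted per-SNP p and the post-removal global p.

**Steiger directionality.** Exposure-side per-SNP R² uses the EAF formula
when frequency is available, otherwise z²/(z²+N); the outcome side (binary,
log-odds scale, where the EAF-based formula is undefined) always uses
z²/(z²+N). Summed R² values are compared as correlation magnitudes through
Fisher's z with the two sample sizes; the direction flag requires strict
dominance of the exposure side, so a tie is "not correct direction" with
p = 1.

**Leave-one-out** recomputes the random-effects IVW J times; a SNP is
flagged influential when its removal flips the estimate's sign or its
significance at 0.05 — an operational rule chosen because qualitative
"this SNP influenced the estimate" statements need a reproducible
definition.

## Study orchestration

Tier classification uses the Bonferroni rule over the k *analyzable*
exposures (those with ≥ 2 harmonized instruments): significant below
0.05/k, suggestive from 0.05/k (inclusive — the boundary goes to the weaker
claim) to 0.05. k is computed, never configured, and printed in the report
so the correction is auditable. Unanalyzable exposures appear in the report
but cannot shift any other exposure's tier.

All randomness flows from one study seed: exposure i draws its sub-seeds
from `SeedSequence(seed, spawn_key=(i,))` (first four 32-bit words → simple
median, weighted median, outlier framework, spare), so single exposures can
be recomputed independently and full reruns are byte-identical. Outputs are
TSV tables (estimates, diagnostics, scatter points, per-method fitted
lines, forest data) plus a sorted-key JSON report; plot rendering is left
to the user.

## Synthetic data

`simulate_pair` generates at the summary-statistic level — no
individual-level genotypes — which is exactly the information two-sample MR
consumes. True γⱼ ~ U(0.5, 1.5)·gamma_scale, positive (instrument lists are
conventionally oriented to the exposure-increasing allele; a symmetric γ
distribution would make "directional" pleiotropy average out of the IVW
slope and would not represent the scenario the robust estimators target).
Γⱼ = β·γⱼ + αⱼ with αⱼ zero (`none`), zero-mean normal (`balanced`), or
mean-shifted (`directional`), applied to a configurable fraction of SNPs;
`inside_violation` adds a component proportional to γⱼ to break InSIDE.
Outliers displace Γⱼ by a chosen multiple of its SE. Observed effects add
noise at the analytic SE (2·EAF·(1−EAF)·N)^(−1/2); the binary outcome is
approximated as a continuous log-odds scale with those SEs, which is
sufficient for estimator calibration (full liability-scale case-control
simulation is out of scope). Defaults — J = 20, N = 50,000 exposure /
138,086 outcome, EAF ~ U(0.05, 0.95), gamma_scale = 0.05 (single-SNP F
broadly in the tens) — emulate a well-powered nutrient-biomarker GWAS
against a large ALS-scale case-control meta-analysis.

What the generator does *not* emulate: LD between instruments (pairwise
independence unless an r² matrix is supplied), sample overlap between the
two GWASs, population stratification, winner's-curse inflation of selected
γ̂, and case-control ascertainment effects. Passing calibration and
recovery tests therefore certifies the estimators and the pipeline
plumbing under the stated generative model, not robustness to those
real-data complications.

## Validation experiments

`mrscreen.validation` (used by the test suite and `scripts/acceptance.py`)
runs, at desk scale on one CPU in well under a minute of aggregate compute:

- **Recovery**: 500 replicates at J = 50, β = 0.1, N = 50k/100k, no
  pleiotropy → mean IVW bias (the small negative residual is
  regression-dilution from γ̂ noise, well under 0.01 here) and 95% CI
  coverage.
- **Calibration**: Q over 2000 null replicates at J = 10 and the global
  outlier test over 1500 null replicates (n_sim = 1000) at J = 20, both
  with strong instruments (gamma_scale 0.1) because the chi-square and
  simulation references treat γ̂ as essentially known; replicate counts are
  sized so Monte-Carlo noise is small against the 0.05 ± 0.02 band.
- **Detection**: one SNP shifted by 10·σ_y among J = 20, 200 replicates →
  rate at which it is flagged with the minimum outlier p; and the
  directional-pleiotropy comparison (40% invalid instruments, mean
  pleiotropic effect 0.05) where the weighted median's absolute bias must
  undercut IVW's.
- **Bookkeeping**: a 35-exposure synthetic screen with six single-SNP
  exposures → k = 29 analyzable, and an exact audit of the
  method-applicability matrix.

## Known limitations

- Egger's CI/p use t(J−2); some implementations use the normal reference —
  differences are visible only at very small J.
- The proxy mechanism relabels the original exposure association rather
  than looking up the proxy's own, an approximation valid at r² > 0.8.
- Steiger's z²/(z²+N) outcome R² is itself an approximation on the observed
  scale, not a liability-scale quantity.
- No multivariable MR, mode-based estimators, radial MR, or contamination
  mixtures; the screen is the univariable five-estimator design.
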