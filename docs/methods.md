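# Methods

This note documents the quantitative model the package implements, the
defaults it ships with, and what its synthetic validation does and does not
demonstrate.

## Quantification model

**Internal-standard method.**  Every mass is a ratio estimate against an
internal standard spiked just before injection (25 ng by default):

    RRF = (A_analyte / A_IS) / (m_analyte / m_IS)        (calibration)
    mass = (A_analyte / A_IS) · m_IS / RRF               (samples)

Two internal standards are carried: `d5-PCB30` is the quantification
reference for OH-PCBs (measured as their methylated MeO-PCB derivatives) and
`PCB204` for PCBs.  Because PCB204 serves as the IS it cannot itself be an
analyte.  Injections of a sample are averaged (arithmetically) before
quantification; calibration injections of one standard are pooled into a
standard-level geometric mean (GM) because they are repeated measures of the
same compound, not independent standards.

**Homologue response model.**  The RRF of a congener without a standard is
predicted from the calibrated congeners sharing its chlorine count:

* *Estimate*: GM of the standard-level GM RRFs of the homologue.  A GM is the
  natural center for RRFs, which are positive and multiplicative-noise
  quantities.
* *Uncertainty*: a seeded bootstrap that resamples **standards** within the
  homologue (B = 2000 by default).  Plain 2.5/97.5 percentile intervals
  undercover badly with the handful of standards a homologue typically has
  (measured ≈ 85% at five standards, against nominal 95%), so the package
  uses the expanded percentile interval — the same resampling with quantiles
  widened to Φ(−√(n/(n−1))·t₀.₉₇₅,ₙ₋₁) — which restores ≈ 93% coverage at
  n = 5 and ≈ 95% by n = 10.  With a single standard the interval degenerates
  to a point, flagged via `n_standards`.
* *Fallback*: a weighted least-squares regression of ln(RRF) on chlorine
  count across all standards (weights = replicate counts) supplies estimates
  for homologues absent from the calibration set, with a bootstrap interval
  from resampling standards globally and a `wide_ci` flag.  Homologues with
  fewer than three standards keep their GM estimate but record the regression
  value alongside.  Both the grouped ("homologues") and regression ("number
  of chlorines in the molecules") readings of the response-prediction idea
  are therefore available; the grouped estimate is primary wherever data
  exist.

The homologue model is fitted on the MeO-PCB standards only.  PCB standards
contribute per-congener RRFs but are kept out of the OH-PCB homologue means,
since the two families are measured in different acquisitions against
different internal standards.

**Homologue assignment.**  An unknown peak's chlorine count is assigned by
comparing its observed isotope cluster with the theoretical binomial
patterns for 0–10 chlorines (³⁵Cl 75.77%, ³⁷Cl 24.23%; C/H/O isotopes
ignored).  A candidate matches when every abundance agrees within a relative
tolerance (default 0.15, absolute floor tolerance/10 for near-zero peaks);
the assignment is reported only when exactly one candidate matches.  At the
default tolerance adjacent homologues can never co-match — neighbouring
patterns differ at the monoisotopic peak by a factor of 0.7577, a 24–32%
relative gap.  Much larger tolerances would make neighbours co-match, which
is deliberately reported as no-match rather than resolved arbitrarily.

**Recovery correction.**  Extraction losses are estimated per sample and
family from isotope-labelled surrogates (spiked 25 ng; di- to
hepta-chlorinated for OH-PCBs, mono- to deca- for PCBs) assumed to have unit
RRF against their family's IS (they are calibrated separately from the
analytes).  An analyte's mass is divided by the recovery of the surrogate
with the nearest chlorine count, ties resolved toward the lower-chlorinated
surrogate.  Recoveries outside [0.25, 2.0] are flagged and logged, never
capped — the correction is applied as measured.

**Limits of quantification and censoring.**  LOQs come only from method
blanks; masses are never blank-subtracted.

* Calibrated congener: `LOQ = x̄ + t(0.95, n−1)·s` over its blank masses.
  The bound uses the standard deviation itself (not s/√n): it is a
  prediction-style upper bound on a single blank contribution, taken
  literally from the defining formula.
* Unknown congeners: one LOQ per matrix,
  `exp(mean(ln L) + t(0.95, n−1)·sd(ln L))` over the *positive* known
  OH-PCB LOQs — the same upper bound on the log scale, always at least their
  geometric mean.
* Censoring uses a strict inequality: a value exactly at the LOQ is
  retained ("below the LOQ" means below).  The alternate `at-or-below`
  boundary is available as a config key.  Censored entries are exact zeros,
  so `concentration == 0 ⇔ censored` in the output table.
* Units follow the matrix and are never mixed: ng/g dry weight for
  sediments (blank masses divided by the blank's sediment-equivalent mass,
  1 g by default), ng/sample for Aroclor mixtures.

## Profiles and similarity

A congener profile is the per-sample vector of concentration fractions over
a canonical ordering: homologue first, then elution order (relative
retention time), then label; PCBs order by congener number.  Profiles are
aligned to the union universe of peaks detected in any sample of the
comparison (absent = 0), and censored zeros participate as true zeros.
Cosine similarity is scale-invariant per sample, so fractions and raw
concentrations give identical cos θ.  Samples with fewer than five detected
congeners are excluded from similarity analysis with a logged warning: with
so few peaks a fraction vector is dominated by censoring artifacts.
Within/between-group summaries (median, mean ± sd) cover all unordered
pairs, diagonal excluded; singleton-only groupings leave the within-group
summary undefined and flagged rather than silently absent.

## Site statistics

Concentrations span orders of magnitude and group sizes are tiny (2–5
samples per site), so the defaults are:

* GM/GSD as the central summaries; censored zeros are excluded from GM and
  other log-based analyses with a logged count, while totals (plain sums)
  use all entries.
* Exact tests with tail-doubled two-sided p-values capped at 1:
  Wilcoxon–Mann–Whitney by full enumeration of all C(n₁+n₂, n₁) rank
  assignments (midranks for ties) for n₁+n₂ ≤ 12, Spearman by full
  enumeration of all n! rank permutations for n ≤ 8.  Above the limits the
  tie-corrected normal/t approximations are used and the method is recorded
  in the result.  Tail doubling reproduces the canonical small-sample
  values: complete separation of 5 vs 5 gives 2/252 = 0.0079; perfect rank
  agreement of five pairs gives 2/120 = 0.017.
* Pearson correlation and OLS regression are computed on ln-transformed
  pairs; the log–log slope β₁ is an elasticity, so a factor-f change in PCBs
  predicts a factor f^β₁ change in OH-PCBs (`fold_change`).
* Significance level 0.05 throughout; no multiple-testing correction is
  applied (none is part of the documented procedure).

## Synthetic-data generator

`generate_study` inverts the quantification model: true concentration →
mass → expected response `RRF_true · (mass·recovery/m_IS) · A_IS`, with
multiplicative lognormal noise per injection.  Noise is multiplicative
everywhere (responses, recoveries, totals) because the emulated quantities
span five orders of magnitude; additive noise would be unphysical.

Defaults, chosen once to emulate a three-site sediment survey:

| parameter | default | meaning |
| --- | --- | --- |
| universe | 275 OH-PCB peaks (70 with standards: 9/5/6/12/13/8/10/6/1/0 per homologue 1–9), 174 PCB peaks | peak lists with deterministic RRTs; includes the named peaks 4-OH-PCB52 (RRT 1.524), 4'-OH-PCB18, 4-OH-PCB2, 2@1.232, 3@1.482 |
| sites | NBH-like (5 samples, OH GM 12 µg/g, GSD 1.25; dominants 4-OH-PCB52 18% + 4'-OH-PCB18 12%), AWL-like (5, 0.38 µg/g, GSD 3.5; 3@1.482 18% + 2@1.232 16%), IHSC-like (2, 0.11 µg/g, GSD 2.5; 3@1.482 26% + 4-OH-PCB2 23%) | totals and dominant-peak shares mirror the survey magnitudes; top-two sums are 30%, 34%, 49% |
| fingerprint tails | 78 congeners per site, lognormal weights σ = 1.8 | heavy-tailed sparse fingerprints; pairwise preset cosines 0.004/0.047/0.377 — the AWL/IHSC pair shares its top peak yet stays below 0.4 |
| `rrf_curve` | ln RRF = 0.5 − 0.12·n_cl + ε, σ_ε = 0.10 | per-congener scatter around the homologue trend; σ_ε is what limits semi-targeted accuracy |
| `replicate_sigma` | 0.05 | lognormal injection noise |
| `profile_jitter_sigma` | 0.4 | per-sample congener-fraction variation within a site |
| `recovery_gm/gsd` | 1.0 / 1.30 | surrogate recoveries near 100% |
| `blank_gm_ng/gsd/cv` | 0.025 / 1.9 / 0.5 | low-level blank contamination; yields known OH-PCB LOQs of a few hundredths of a ng/g and an unknown-congener sediment LOQ near 0.15 ng/g by construction |
| design | 6 blanks, sextuplicate calibration, duplicate sample injections, 25 ng spikes | QA defaults |

All randomness flows from one study seed through named substreams
(calibration / blanks / per-sample), so adding samples never perturbs the
calibration or blank draws.  Site fingerprints are drawn from a stream keyed
by the site name alone, making a preset's "true" profile a fixed property of
the preset rather than of the study seed.  Internal-standard responses in
samples are taken as constant (injection-level scale factors cancel in the
response ratio; the residual effect of averaging injections is second-order
and ignored).

**What passing the synthetic validation shows — and what it does not.**
On generated studies the pipeline recovers uncensored concentrations with a
median relative error under 10% (dominated by the per-congener RRF scatter
σ_ε = 0.10, since congeners without standards inherit exactly that error),
recovers site GM totals, and separates within-site from between-site
congener fingerprints.  The generator emulates lognormal response noise, a
smooth homologue response trend, blank contamination, and recovery losses
that affect analytes and surrogates identically.  It does not emulate:
retention-time drift or misidentified peaks; coeluting congeners; matrix
effects that differ between analytes and surrogates (which would bias the
recovery correction undetectably); instrument drift between calibration and
samples; non-lognormal heavy-tailed contamination; or any coupling between
OH-PCB and PCB totals (sites draw them independently, so the generated data
carry no log–log relationship to recover — the regression machinery is
validated on directly generated pairs instead).  Real-data accuracy
therefore depends on how well a homologue's calibrated congeners represent
its uncalibrated ones, which no synthetic test can establish.

## Numerical and design choices

* Unknown-label grammar fixed at `<n_cl>@<rrt>` with RRT to three decimals;
  ties in RRT break by label.  Coeluting congeners are one analyte keyed by
  the joined label; they must share a homologue, and a coelution spanning
  homologues is an explicit error rather than a guess.
* CSV dialect: comma-separated, UTF-8, `.` decimal; the prime in
  4′-OH-PCB18 is accepted as U+2032 or ASCII `'` and emitted as `'`.
* The calibration CSV carries internal-standard rows (labels `d5-PCB30`,
  `PCB204`); the reader splits them from analyte standards.
* Bootstrap seeds: one seed per fit; fixed seed ⇒ identical intervals.
  Bootstrap interval bounds are clipped to bracket the point estimate (a
  guard against degenerate resample sets).
* `mann_whitney_exact` and `spearman_exact` treat values within 1e-9 (ranks
  within 1e-12) as tied when accumulating enumeration tails, guarding
  against float round-off in midranks.
* Exact-test size thresholds (12 and 8) keep enumeration under a millisecond
  per test; they are config keys, not hard limits.
* Degenerate inputs are explicit errors, not NaNs: empty groups, constant
  vectors (Spearman), nonpositive values in log-based statistics, all-zero
  samples in profile building, zero-norm vectors in cosine.

## Known limitations

* The recovery correction assumes the nearest-homologue surrogate is
  representative; no interpolation across surrogates is attempted.
* The unknown-congener LOQ is one number per matrix; congener-specific
  blank behaviour of unknowns is not modelled (their blank levels inform
  nothing beyond the known-congener pool).
* The homologue regression fallback is linear in chlorine count on the log
  scale; curvature in the true response trend would bias predictions for
  homologues far from the calibrated range, which is why extrapolated
  predictions carry a `wide_ci` flag.
* Exact tests above the enumeration limits fall back to asymptotic
  approximations that are anti-conservative for very small samples; the
  limits are set so this cannot happen silently (the method field says
  which path ran).
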