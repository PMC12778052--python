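# Methods

## Problem setting

A single dose of a receptor-targeted ADC is given to tumor-bearing mice.
A PET tracer binding the same target is imaged at baseline and several
days after dosing; the fractional drop in tumor uptake estimates how
much of the target the drug engaged (target engagement, TE). Tumor
volumes are measured by caliper for two weeks and classified into
response categories; the analysis then asks whether TE, measured
noninvasively, predicts response, and locates the TE cutoff that best
separates responders from nonresponders.

## Quantitation conventions

* **Decay correction.** Activities are referenced to injection time:
  A_ref = A_measured · 2^(Δt / T½), with the gallium-68 half-life fixed
  at T½ = 67.71 min (physical constant). Negating Δt decays forward, so
  the operation is exactly invertible (round-trip tested to 1e−12
  relative tolerance). Dead-time correction is assumed done upstream by
  the counter/scanner.
* **%IA/g.** Counting standards represent a known fraction of the
  injected dose; the decay-corrected mean standard divided by that
  fraction calibrates counts per 100% of injected activity. Because the
  same decay reference multiplies numerator and denominator, %IA/g is
  invariant to the common reference time chosen — a tested property.
* **SUV.** Rodent g/cc convention: SUV = (%IA/cc ÷ 100) × body weight
  (g). A uniformly distributed tracer gives SUV ≈ 1.
* **Tissue ratios.** Tumor-to-blood and tumor-to-muscle ratios are
  formed within each animal and then averaged (mean-of-ratios). The
  alternative ratio-of-means is not equivalent — for per-animal pairs
  (4, 1) and (3, 3) the two give 2.5 vs 1.75 — and the per-animal
  construction is the one consistent with how paired biodistribution
  tables are built. Animals with zero denominator uptake are excluded
  with a logged warning, never silently.
* **logD.** Mean over replicates of log10(octanol counts / PBS counts);
  zero-count replicates are excluded with a warning.

## PD metrics

accessible % = 100·SUV_post/SUV_pre and TE % = 100·(SUV_pre −
SUV_post)/SUV_pre. The identity accessible + TE = 100 holds exactly for
every valid input and is asserted as a property test. TE is
scale-invariant in the SUV pair, equals 100 only for complete uptake
loss, and is deliberately not clipped: negative TE (uptake above
baseline) is a meaningful "no engagement" observation, and ΔSUV =
SUV_post − SUV_pre keeps the raw-change sign convention (negative when
uptake falls). SUV_mean drives the default analysis with SUV_max
supported in parallel; the two track each other in both measured and
simulated data.

## mRECIST classification

ΔVol_t = 100·(V_t − V_0)/V_0 with the day-0 element exactly zero.
BestResponse is the minimum ΔVol over days ≥ 10 (boundary inclusive);
BestAvgResponse is the minimum over eligible days t of the average of
ΔVol from day 0 through t inclusive — day 0's zero participates in
every prefix. Class cutoffs (all strict, first match wins): mCR −95/−40,
mPR −50/−20, mSD 35/30, else mPD. The (−96, −48) case satisfies the
mPR and mSD rules too; precedence must return mCR and is asserted
explicitly. Responder coding: mPD → 0, anything better → 1.

Two subtleties the tests pin down: a prefix average can never undercut
the curve's pointwise minimum (mean ≥ min on any prefix), and
classification is monotone under pointwise dominance — a curve that
sits at or below another on every shared day can never receive a worse
label. Animals with no measurement at or after day 10 are reported as
unclassifiable and excluded from downstream ROC with a count in the
report provenance; they are never defaulted or dropped silently.

## ROC / Youden threshold

The decision rule is "predict responder when score ≥ threshold";
thresholds are a +∞ sentinel followed by the unique observed scores in
descending order, so tied scores collapse to one ROC point and the
curve starts at (0, 0) and ends at (1, 1). AUC is the trapezoidal area
under (FPR, TPR), which under this enumeration equals the Mann-Whitney
pairwise concordance probability with half credit for ties; the two are
compared exactly on 200 random small cohorts, and scikit-learn's
implementation is used as an additional independent cross-check.

The Youden-optimal threshold maximizes J = TPR − FPR; among ties the
smallest maximizing threshold is returned, which admits the most
animals into the predicted-responder stratum (maximizes sensitivity)
and makes the choice deterministic. The sentinel guarantees J ≥ 0.

Score orientation is never auto-detected: higher score must mean "more
likely responder", and callers negate lower-is-better scores (such as
post-treatment SUV) explicitly. An anti-predictive score therefore
reports its AUC below 0.5 faithfully rather than being flipped — the
honest behavior when comparing candidate biomarkers.

Stratified responder rates at a threshold report percentage and
(responders, total) counts in the score < threshold and score ≥
threshold strata; an empty stratum's rate is undefined (None), not 0.

## Synthetic cohort generator

The generator emulates the study design rather than fitting any curve
to data. Defaults (all configurable, `petpd config-init` prints them):

| parameter | default | meaning |
|---|---|---|
| n_per_group / doses | 10 at 6 and 15 mg/kg | two single-dose arms |
| n_saline | 5 | temporal/treatment controls |
| te_bin_edges | 0, 5, 25, 50, 100 | engagement strata (%) |
| te_bin_weights (6 mg/kg) | 0.40, 0.30, 0.20, 0.10 | low-dose mixture |
| te_bin_weights (15 mg/kg) | 0.10, 0.20, 0.30, 0.40 | high-dose mixture |
| saline_te_sd | 5 | zero-centered TE noise, untruncated |
| threshold_pct | 30 | engagement step for response |
| p_response_below / at_or_above | 0.0 / 0.875 | step response model |
| baseline_volume_mean_mm3 (CV) | 170 (0.13) | baseline tumor volume |
| growth rate, nonresponder | 0.09 ± 0.02 /day | exponential growth |
| growth rate, responder | −0.02 ± 0.03 /day | slow shrinkage |
| measurement_days | 0, 3, 7, 10, 14 | caliper schedule |
| volume_noise_cv / suv_noise_cv | 0.08 | multiplicative lognormal |
| suv_pre_mean (CV) | 0.8 (0.20) | baseline tumor SUV |

True TE is drawn by picking an engagement bin with the dose-specific
weight and then uniformly within the bin; the per-dose weights are a
calibration chosen so the pooled bin occupancy approximates the
reported pooled strata (≈6 animals below 5% and ≈5 in 5–25% across both
arms, with the high-dose arm shifted toward the upper bins) — the
per-dose breakdown is not published, so these are the generator's own
choice, not data. Response is Bernoulli with a hard step at the
threshold, matching the reported stratified rates (0% below, 87.5% at
or above); a logistic alternative (`response_model: logistic`,
midpoint at the threshold) is available for sensitivity analyses.

Growth is V(t) = V₀·e^{gt} with multiplicative lognormal measurement
noise on every day but baseline. The exponential law and its rates are
invented plumbing: they exist so the mRECIST classifier reproduces the
intended labels. With the default rates a noise-free responder
(g = −0.02) reaches ΔVol ≈ −24% by day 14 (mSD) and a noise-free
nonresponder (g = 0.09) reaches ≈ +252% (mPD); the rate spreads put a
small tail of each group across the classification boundary, so derived
labels agree with generative labels for ≈96% of animals — quality-gated
at ≥ 90% over 500 simulated cohorts rather than assumed.

Observed SUVs: latent SUV_pre is lognormal (parameterized by arithmetic
mean and CV); latent SUV_post = SUV_pre·(1 − TE/100), floored at 1e−6
when TE = 100; both observed through independent mean-1 lognormal
noise. Observed TE is then slightly biased toward lower values — the
noise ratio has mean e^{σ²} with σ² = ln(1 + CV²), giving a bias bound
of (e^{σ²} − 1)·(100 − TE) ≈ 0.4 points at TE = 40 — which the
unbiasedness test tolerates explicitly instead of hiding.

Reproducibility: each animal's random substream is seeded by
SHA-256(animal_id) combined with the root seed, so identical
(config, seed) reproduce byte-identical CSVs and enlarging the cohort
never reshuffles existing animals.

What the generator does *not* emulate: ADC pharmacokinetics, payload
release or bystander effects, tumor heterogeneity in tracer delivery,
scanner resolution effects, or correlated pre/post measurement error.
Passing tests show the analysis chain is correct and self-consistent
under the stated generative model; they do not validate the biological
model itself against animal data.

## Numerical and design choices

* Thresholds and cutoffs follow the strict-inequality phrasing of the
  classification rules; the day-10 eligibility boundary is inclusive.
* The analytic AUC oracle integrates the TE mixture density and the
  response model on a uniform grid (2×10⁵ points, midpoint tie
  correction); the simulated AUC at 10⁵ animals must agree within 3
  standard errors (Hanley-McNeil).
* Problem sizes: threshold-recovery runs use 1,000 animals per arm
  (saline excluded, as controls carry no engagement signal); quality
  gates pool 500 study-sized cohorts. These sizes put Monte-Carlo error
  well inside the tolerances being tested.
* The pipeline classifies whatever curves it is given — saline animals
  are not special-cased; with the default generator they are all mPD.
* Single-class cohorts (all responders or all nonresponders) skip the
  ROC with an explicit notice and exit code 3 in the CLI, since
  TPR or FPR would be undefined.

## Known limitations

* The Youden threshold estimated from study-sized cohorts (8
  responders) is highly variable — the worked example lands at 44% with
  the generative step at 30%; only the large-cohort recovery pins the
  step down. This mirrors the general caution that small-n ROC cutoffs
  are unstable.
* BestAvgResponse weights all days equally regardless of spacing; an
  irregular schedule front-loads the average toward densely sampled
  periods.
* TE from SUV ratios inherits any pre-to-post change in tracer
  delivery (perfusion, tumor size) that is not receptor engagement;
  the pipeline cannot distinguish occupancy from target loss.
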