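# Methods

## Viable tumor volume quantification

The imaging pipeline assumes the arterial-phase enhanced and unenhanced
volumes are co-registered on the same grid (shape and voxel spacing are
checked; registration itself is out of scope). The enhancement map is the
plain voxelwise difference, which makes the whole pipeline invariant to any
constant intensity offset shared by the two acquisitions. The parenchyma
threshold is the mean enhancement at ≥3 operator-chosen reference points in
healthy liver; each point is averaged over a cubic neighborhood whose radius
is configurable (default 1, i.e. a 3×3×3 mean) because single-voxel sampling
is needlessly noise-sensitive — radius 0 reproduces literal point sampling.
Viable tumor (Seg2) is the subset of the whole-tumor mask (Seg1) with
enhancement *strictly greater* than the threshold; volumes are voxel count ×
voxel volume, reported in cm³, with anisotropic spacing supported. Only the
arterial phase contributes to the threshold.

## Response criteria

All change quantities are percentages, (follow-up − baseline)/baseline × 100,
bounded below by −100; fractional representations are deliberately kept out
of the API. mRECIST categories are assessed against baseline (single
follow-up design, no nadir): a new lesion forces PD ahead of everything else,
complete disappearance of target enhancement is CR, ≥ +20% is PD, ≤ −30% is
PR, else SD; responders are CR ∪ PR. The volumetric criterion is a pure
dichotomy: responder ⇔ VC ≤ cutoff (default −57.0, boundary inclusive) and no
new lesion; no separate CR/PD grades are modelled on the volume scale. When a
patient has several target lesions, their viable volumes are summed before
the change is computed, mirroring the diameter-sum convention.

Agreement between the two responder calls uses Cohen's kappa with the
large-sample (asymptotic) 95% CI, banded poor/moderate/excellent at 0.4 and
0.75, and McNemar's test on the discordant cells — exact binomial when there
are fewer than 25 discordant pairs, chi-square without continuity correction
otherwise. A table with all mass in one cell of both margins makes kappa
undefined; it is reported as degenerate rather than silently NaN.

## Cutoff derivation

The hazard of death is modelled by a Cox partial likelihood (Efron ties) on a
restricted cubic spline basis of VC: the identity plus k−2 truncated-power
terms normalized by (t_k−t_1)², constructed to be exactly linear beyond the
boundary knots. Knots default to the 0.05/0.35/0.65/0.95 quantiles of the
observed VC (the standard placement for four knots); both knots and the
reference value are configurable. Patients with new lesions are excluded from
the derivation (they are PD by definition and would contaminate the
VC–hazard relation) but are retained downstream as non-responders.

Two numerical choices matter in practice:

- **Conditioning.** The basis columns are standardized before the fit (and
  the coefficients/covariance rescaled after). With a clumped VC distribution
  — complete responders pile up at −100 while growth stretches the right
  tail — adjacent knots crowd together and the nonlinear terms become nearly
  collinear (pairwise correlations > 0.999), which stalls plain
  Newton–Raphson. A small ridge penalty (10⁻⁴ on the standardized scale,
  configurable, removable) restores convergence with negligible shrinkage.
  Columns that are exactly collinear (e.g. only two distinct VC values) are
  dropped by rank detection, in which case the fit gracefully reduces to an
  ordinary (two-group) Cox fit.
- **The hazard-ratio reference.** "HR = 1" is only defined relative to a
  comparator; the cohort median VC is used by default. With a monotone fitted
  curve the crossing then sits at that median — the procedure effectively
  asks "where does the typical response separate protective from harmful?" —
  while a non-monotone curve can cross several times. The crossing search
  samples the curve on a 0.5-point grid over the observed VC range, refines
  every sign change by bracketed root-finding (tolerance 10⁻³), and reports
  all roots. When several exist, the reported cutoff is the up-crossing that
  best separates the observed cohort into HR ≤ 1 below and HR ≥ 1 above
  (ties broken toward the steeper ascent); a local-slope criterion alone
  proved fragile, as small tail wiggles of a cubic can be arbitrarily steep.
  If the curve never crosses 1 in range, a no-crossing error carries the
  sampled curve for inspection. Pointwise curve CIs are delta-method on the
  coefficient covariance.

## Survival evaluation

Cohorts are split 7:3 (training size = round(0.7·n), seeded). KM medians use
log-log (Brookmeyer–Crowley-style) CIs; a curve that never reaches 0.5
yields an undefined median, reported as NA. The multivariable models enter
metastasis, PVTT and the responder flag as binaries and subsequent treatment
as a single ordinal 0–3 term (none/locoregional/systemic/combined), so a
fitted model is fully described by four named coefficients and its linear
predictor is their dot product with the coded covariates. A warning is
emitted below 10 events per variable. An optional univariate screen
(single-covariate Cox, p < 0.05 by default) is provided for covariate entry.

Discrimination and calibration:

- **Harrell's C** is computed by direct pair enumeration (usable pairs: the
  earlier time is an event, or tied times with exactly one event; predictor
  ties score ½) with a delta-method U-statistic SE — analytic, not bootstrap.
- **Time-dependent AUROC** uses the IPCW cumulative-cases/dynamic-controls
  estimator (censoring distribution from the training data), with a seeded
  bootstrap percentile CI (default 500 resamples); a naive
  observed-cases/controls estimator is available and coincides with the IPCW
  one under no censoring. Default horizons: 6, 12, 24 months.
- **Calibration** compares predicted survival, S(t|x) = exp(−H₀(t)·e^LP)
  with a Breslow baseline estimated on the training cohort, against the KM
  estimate within predicted-risk tertiles (binning is configurable; a
  constant predictor collapses to one group). Groups whose follow-up does not
  reach the horizon are flagged, not dropped. The Breslow baseline is paired
  with Efron-tie coefficient estimates; with the near-continuous survival
  times used here the discrepancy is immaterial.

## Synthetic data

**Phantoms.** A voxelized ellipsoid tumor (default semi-axes 20/15/10 mm on a
64³ 1 mm grid) in homogeneous parenchyma; an inner concentric ellipsoid
scaled by (1−f)^(1/3) is necrotic so the viable shell holds fraction f of the
tumor. Enhancement means (viable 120, parenchyma 50, necrotic 10, arbitrary
units) are ordered so the parenchyma threshold separates compartments;
i.i.d. Gaussian noise is added to both acquisitions. The generator returns
the exact viable voxel count as truth, so zero-noise recovery is exact up to
the threshold rule. Not emulated: partial-volume effects, texture, motion,
modality-specific calibration — phantom results bound algorithmic, not
clinical, accuracy.

**Cohorts.** Covariates are independent Bernoulli/categorical draws at the
prevalences of a TACE-treated HCC population (metastasis 0.20, PVTT 0.18,
subsequent treatment 0.52/0.295/0.0925/0.0925). Baseline diameters are
lognormal (median 5 cm); baseline viable volumes scale with the diameter
cubed times a shape factor. The diameter change DC is Gaussian (sd 25); the
actual volume change is VC = 1.88·EVC(DC) + 69.75 + ε, clipped at −100 —
the empirically observed departure from the cube law, with ε chosen at sd 45
so that mRECIST/mqEASL agreement lands in the moderate-kappa regime
(κ ≈ 0.65) reported for real cohorts; a small sd would make the two markers
near-duplicates, which real data contradict. Complete disappearance
(probability 0.05) forces DC = VC = −100; new lesions (probability 0.10) are
drawn independently.

Event times follow a proportional-hazards model with piecewise-constant
baseline (default a single piece, rate ln 2/40 per month) and log hazard
β_m·met + β_p·pvtt + β_s·subs + g(VC), with covariate effects at the
volumetric model's published-scale values (1.88, 0.92, −0.36). By default
g is linear, 0.0125·(VC − crossing): the slope is chosen so that the implied
responder-vs-non-responder contrast (≈ 0.0125 × the ~110-point mean VC gap
across the −57 boundary) matches a responder log-HR near −1.4. A "responder"
mode replaces g with a step effect −1.41 on the true volumetric responder
label for coefficient-recovery studies. The crossing is planted by
construction: when the DC mean is unspecified it is calibrated — on a
deterministic quantile grid, independent of any draw — so the population
median VC equals the target crossing (default −57), which is exactly the
quantity the median-referenced spline procedure estimates. Censoring is a
staggered-entry administrative window, uniform on 60–144 months, plus
optional exponential dropout; the defaults give ≈ 18% censoring and a
marginal median OS ≈ 22 months. Everything is a pure function of the spec
and seed.

What passing tests show — and do not. Recovery of the planted crossing
(median absolute error ≈ 4 points over 50 cohorts of n = 500) demonstrates
that the estimator is consistent for the boundary it targets under
proportional hazards with independent censoring; it says nothing about
unmeasured confounding, informative censoring, or measurement error in VC,
none of which the generator emulates. Likewise the directional Model 2 ≥
Model 1 comparison holds *because* the simulated hazard is driven by the
volume change; it is a consistency check of the machinery, not clinical
evidence.

## Problem sizes and defaults used in checks

Replicated checks use 50 cohorts of n = 500 (cutoff recovery), n = 2000
single cohorts (coefficient recovery, calibration), 50 replicates of n = 400
split 7:3 (marker comparison), and 64³ phantoms — sizes at which the Monte
Carlo error is comfortably inside the asserted tolerances while the full
suite stays fast.

## Known limitations

- Seg1 (whole-tumor outline) is an input; no interactive or automatic
  whole-tumor segmentation is provided, and no registration between phases.
- The cutoff carries no confidence interval, and optimal-cutpoint methods
  (e.g. maximally selected rank statistics) are deliberately not implemented;
  the HR = 1 crossing with a median reference is the estimand.
- With a median reference and a monotone hazard curve the derived cutoff
  tracks the cohort's median response; cohorts whose typical response differs
  from the planted −57% will, correctly, yield a different cutoff.
- Multiplicity of target lesions is handled by summing volumes; no
  per-lesion weighting.
- The C-index SE is analytic; bootstrap SEs may differ slightly in small
  samples.
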