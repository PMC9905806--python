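# mqeasl

Volumetric viable-tumor response assessment for hepatocellular carcinoma (HCC)
treated with transarterial chemoembolization (TACE), and a head-to-head
comparison of diameter-based and volume-based response markers as predictors
of overall survival.

## The problem

After TACE, treatment response is conventionally graded with mRECIST: the
percent change in the sum of the longest diameters of *enhancing* (viable)
tumor, with a −30% bar for partial response. Tumors necrose irregularly, so a
single diameter is a poor proxy for the residual viable burden. The
quantitative EASL (qEASL) approach instead segments the viable tumor in 3D —
voxels of the whole-tumor mask whose arterial-phase enhancement exceeds that
of healthy parenchyma — and measures the viable tumor volume (VTV) in cm³.

If lesions shrank as uniform spheres, a diameter change DC would imply an
expected volume change

    EVC = [(1 + DC/100)³ − 1] × 100 (%)

so the classical −30% diameter bar maps to a −65.7% volume bar. Real cohorts
deviate substantially from the cube law (the observed relation is close to
VC = 1.88·EVC + 69.75), so this package derives the volumetric responder
cutoff *from survival data*: a Cox proportional-hazards model expresses the
log hazard of death as a four-knot restricted cubic spline in the viable
volume change VC, and the VC at which the fitted hazard-ratio curve crosses
HR = 1 (relative to the cohort median) is adopted as the cutoff — the
boundary where further residual viable tumor turns from protective to
harmful. The resulting criterion ("mqEASL": responder ⇔ VC ≤ −57% and no new
lesion) is then compared against mRECIST by Kaplan–Meier/log-rank analysis
and by multivariable Cox models

    Model 1 (diameter marker):  LP = β₁·Metastasis + β₂·PVTT + β₃·SubsequentTreatment + β₄·Responder(mRECIST)
    Model 2 (volume marker):    LP = β₁·Metastasis + β₂·PVTT + β₃·SubsequentTreatment + β₄·Responder(mqEASL)

scored with Harrell's C, time-dependent AUROC (IPCW cumulative/dynamic) and
calibration tables.

Because no patient data ship with the package, a synthetic-data module
generates (a) imaging phantoms with a known viable volume and (b) survival
cohorts with a planted HR = 1 crossing and known covariate effects, so every
stage is testable end to end.

## Worked example

```python
import mqeasl as mq

# --- imaging: quantify viable tumor volume on a noisy phantom ---
phantom = mq.generate_phantom(mq.PhantomSpec(viable_fraction=0.7, noise_sd=5.5, seed=3))
refs = mq.default_reference_points(phantom.seg1, seed=3)
res = mq.quantify_viable_tumor(phantom.enhanced, phantom.unenhanced, phantom.seg1, refs)
print(res.threshold, res.vtv_cm3, phantom.true_vtv_cm3)
# threshold 49.92  vtv 8.80 cm³  (true 8.80 cm³ of a 12.57 cm³ tumor)

# --- cohort: classify responses and derive the volumetric cutoff ---
records, truth = mq.generate_cohort(mq.CohortSpec(n=500, seed=1))
ann = mq.annotate_cohort(records)   # appends DC/VC/EVC and responder flags
agr = mq.agreement(zip(ann.mrecist_responder, ann.mqeasl_responder))
print(agr.kappa)                     # 0.680 -> "moderate" agreement
cut = mq.derive_cutoff(ann)          # spline Cox fit + HR=1 crossing
print(cut.cutoff_percent)            # -57.4 (planted crossing: -57.0)

# --- survival: compare the two markers ---
train, valid = mq.split_cohort(ann, ratio=0.7, seed=1)
m1 = mq.ResponseCoxModel(train, response_marker="mrecist").fit()
m2 = mq.ResponseCoxModel(train, response_marker="mqeasl").fit()
print(m2.summary().round(3))
print(m1.concordance(valid), m2.concordance(valid))
# validation C-index: 0.708 ± 0.048 (Model 1) vs 0.744 ± 0.045 (Model 2)
```

On this cohort the volumetric marker separates survival sharply (median OS
50.2 vs 13.1 months for mqEASL responders vs non-responders, log-rank
p ≈ 1e-16) and Model 2 dominates Model 1 in both concordance and 12-month
AUROC (0.785 vs 0.749) — the volume marker tracks the hazard-generating
volume change directly, while the diameter marker sees it only through the
noisy cube-law link.

The same pipeline is scriptable from the shell:

```bash
mqeasl simulate --n 500 --seed 1 --out cohort.csv
mqeasl assess cohort.csv
mqeasl derive-cutoff cohort.annotated.csv --out cutoff.json
mqeasl evaluate cohort.annotated.csv --split-seed 1 --out performance.json
mqeasl quantify enhanced.nii.gz unenhanced.nii.gz seg1.nii.gz refs.csv
```

## Layout

- `mqeasl.imaging` — qEASL quantification (subtraction, parenchyma threshold,
  viable segmentation, volume), NIfTI/CSV I/O.
- `mqeasl.response` — percent changes, cube-law EVC, mRECIST and mqEASL
  classification, kappa/McNemar agreement, EVC–VC regression.
- `mqeasl.cutoff` — restricted cubic spline basis, `VolumeCutoffCox` model,
  HR = 1 crossing search.
- `mqeasl.survival` — cohort split, KM/log-rank, `ResponseCoxModel`,
  Harrell's C, time-dependent AUROC, Breslow calibration.
- `mqeasl.simulate` — phantom and cohort generators with truth sidecars.
- `mqeasl.cli` — the `mqeasl` command.

See `docs/methods.md` for the modelling assumptions, default parameters and
their rationale, and known limitations.
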