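"""Synthetic inputs with known ground truth for every pipeline stage.

Two generators replace the unavailable patient material:

* **Imaging phantoms** — a voxelized ellipsoid tumor inside homogeneous
  parenchyma. An inner concentric ellipsoid is necrotic and the surrounding
  shell is viable, scaled so the shell holds a prescribed fraction of the
  tumor volume. Enhancement means are ordered viable > parenchyma > necrotic
  so the parenchyma threshold separates the compartments by construction.
  The exact viable voxel count is returned as ground truth.

* **Survival cohorts** — covariates drawn at the prevalences of a TACE-treated
  HCC population (metastasis ~20%, PVTT ~18%, subsequent treatment
  none/locoregional/systemic/combined ~52/29/9/9%); a diameter change per
  patient; actual volume change generated from the cube-law expected change
  through a linear link (default slope 1.88, intercept 69.75) plus noise; and
  event times from a proportional-hazards model whose volume-change effect is
  a smooth monotone curve anchored so the hazard ratio equals 1 at a
  configurable crossing (default -57%). Censoring is administrative — a
  staggered-entry uniform follow-up window, optionally plus exponential
  dropout — giving roughly an 80% event fraction.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats

from .exceptions import ValidationError
from .imaging import BinaryMask3D, ReferencePointSet, ScalarVolume3D

__all__ = [
    "PhantomSpec",
    "PhantomSet",
    "generate_phantom",
    "default_reference_points",
    "CohortSpec",
    "generate_cohort",
    "generate_paired_measurements",
]

LN2 = float(np.log(2.0))


# ---------------------------------------------------------------------------
# Imaging phantoms


@dataclass
class PhantomSpec:
    """Construction parameters of an ellipsoid viable/necrotic tumor phantom."""

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    center_mm: tuple[float, float, float] | None = None
    semi_axes_mm: tuple[float, float, float] = (20.0, 15.0, 10.0)
    viable_fraction: float = 0.7
    parenchyma_unenhanced: float = 100.0
    parenchyma_enhancement: float = 50.0
    viable_enhancement: float = 120.0
    necrotic_enhancement: float = 10.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.viable_fraction <= 1.0:
            raise ValidationError("viable fraction must lie in [0, 1]")
        if not (
            self.viable_enhancement > self.parenchyma_enhancement > self.necrotic_enhancement
        ):
            raise ValidationError(
                "enhancement means must satisfy viable > parenchyma > necrotic"
            )
        if self.noise_sd < 0:
            raise ValidationError("noise sd must be non-negative")


@dataclass
class PhantomSet:
    enhanced: ScalarVolume3D
    unenhanced: ScalarVolume3D
    seg1: BinaryMask3D
    viable_mask: BinaryMask3D
    true_vtv_cm3: float


def _ellipsoid_mask(shape, spacing, center_mm, semi_axes_mm) -> np.ndarray:
    coords = [np.arange(n) * s for n, s in zip(shape, spacing)]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    cx, cy, cz = center_mm
    ax, ay, az = semi_axes_mm
    r2 = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 + ((zz - cz) / az) ** 2
    return r2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> PhantomSet:
    """Build the paired enhanced/unenhanced volumes, Seg1 and the viable truth."""
    shape = tuple(spec.shape)
    spacing = tuple(spec.spacing)
    extent = [(n - 1) * s for n, s in zip(shape, spacing)]
    center = (
        tuple(e / 2.0 for e in extent) if spec.center_mm is None else tuple(spec.center_mm)
    )
    for c, a, e in zip(center, spec.semi_axes_mm, extent):
        if c - a < 0 or c + a > e:
            raise ValidationError("tumor ellipsoid does not fit inside the grid")

    seg1 = _ellipsoid_mask(shape, spacing, center, spec.semi_axes_mm)
    # inner (necrotic) ellipsoid scaled so the viable shell holds the target fraction
    inner_scale = (1.0 - spec.viable_fraction) ** (1.0 / 3.0)
    if inner_scale > 0:
        necrotic = (
            _ellipsoid_mask(
                shape, spacing, center, tuple(a * inner_scale for a in spec.semi_axes_mm)
            )
            & seg1
        )
    else:
        necrotic = np.zeros(shape, dtype=bool)
    viable = seg1 & ~necrotic

    enh_clean = np.full(shape, spec.parenchyma_enhancement, dtype=float)
    enh_clean[viable] = spec.viable_enhancement
    enh_clean[necrotic] = spec.necrotic_enhancement

    rng = np.random.default_rng(spec.seed)
    unenh = np.full(shape, spec.parenchyma_unenhanced, dtype=float)
    if spec.noise_sd > 0:
        noise_u = rng.normal(0.0, spec.noise_sd, shape)
        noise_e = rng.normal(0.0, spec.noise_sd, shape)
    else:
        noise_u = noise_e = 0.0
    voxvol = float(np.prod(spacing))
    seg1_mask = BinaryMask3D(seg1.astype(np.uint8), spacing=spacing)
    viable_mask = BinaryMask3D(viable.astype(np.uint8), spacing=spacing)
    return PhantomSet(
        enhanced=ScalarVolume3D(unenh + enh_clean + noise_e, spacing=spacing),
        unenhanced=ScalarVolume3D(unenh + noise_u, spacing=spacing),
        seg1=seg1_mask,
        viable_mask=viable_mask,
        true_vtv_cm3=viable_mask.count() * voxvol / 1000.0,
    )


def default_reference_points(
    seg1: BinaryMask3D, n_points: int = 3, radius: int = 1, margin: int = 2, seed: int = 0
) -> ReferencePointSet:
    """Pick parenchyma reference voxels well clear of the tumor mask."""
    pad = radius + margin
    keepout = ndimage.binary_dilation(
        seg1.values.astype(bool), structure=np.ones((2 * pad + 1,) * 3, dtype=bool)
    )
    ok = ~keepout
    # exclude a border so the whole neighborhood stays in bounds
    border = np.zeros(seg1.shape, dtype=bool)
    sl = tuple(slice(radius, s - radius) for s in seg1.shape)
    border[sl] = True
    candidates = np.argwhere(ok & border)
    if len(candidates) < n_points:
        raise ValidationError("not enough parenchyma voxels for reference points")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=n_points, replace=False)
    return ReferencePointSet(
        [tuple(map(int, candidates[i])) for i in idx], neighborhood_radius_voxels=radius
    )


# ---------------------------------------------------------------------------
# Survival cohorts


@dataclass
class CohortSpec:
    """Generative model of a TACE-treated HCC survival cohort.

    The volume-change hazard effect is either a smooth monotone log-linear
    curve ``g(VC) = slope * (VC - crossing)`` (``vc_effect="linear"``, the
    default, whose hazard ratio relative to the planted crossing equals 1
    exactly at the crossing), or a step effect of the true volumetric
    responder label (``vc_effect="responder"``). When ``dc_mean`` is None it
    is calibrated deterministically so the population median VC sits at the
    crossing, which anchors the spline-derived cutoff there.
    """

    n: int = 500
    # covariates (Table-level prevalences of the emulated population)
    p_metastasis: float = 0.20
    p_pvtt: float = 0.18
    subsequent_treatment_probs: tuple = (0.52, 0.295, 0.0925, 0.0925)
    # baseline tumor burden
    d_bl_median_cm: float = 5.0
    d_bl_log_sd: float = 0.5
    vtv_shape_factor: float = 0.4
    vtv_bl_log_sd: float = 0.4
    # response generation
    dc_mean: float | None = None
    dc_sd: float = 25.0
    vc_slope: float = 1.88
    vc_intercept: float = 69.75
    vc_noise_sd: float = 45.0
    p_new_lesion: float = 0.10
    p_complete_disappearance: float = 0.05
    # hazard model
    crossing_vc: float = -57.0
    vc_effect: str = "linear"  # "linear" | "responder" | "none"
    vc_log_hr_per_percent: float = 0.0125
    beta_responder: float = -1.41
    beta_metastasis: float = 1.88
    beta_pvtt: float = 0.92
    beta_subsequent: float = -0.36
    baseline_hazard: tuple = ((0.0, LN2 / 40.0),)  # (start_month, rate) pieces
    censoring_rate_per_month: float = 0.0  # optional loss-to-follow-up dropout
    censor_window_months: tuple[float, float] = (60.0, 144.0)  # staggered-entry admin window
    seed: int = 0

    def __post_init__(self):
        probs = [self.p_metastasis, self.p_pvtt, self.p_new_lesion,
                 self.p_complete_disappearance, *self.subsequent_treatment_probs]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValidationError("all probabilities must lie in [0, 1]")
        if abs(sum(self.subsequent_treatment_probs) - 1.0) > 1e-9:
            raise ValidationError("subsequent treatment probabilities must sum to 1")
        if self.vc_effect not in ("linear", "responder", "none"):
            raise ValidationError("vc_effect must be 'linear', 'responder' or 'none'")
        if self.n < 1:
            raise ValidationError("cohort size must be at least 1")
        starts = [s for s, _ in self.baseline_hazard]
        if starts[0] != 0.0 or any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValidationError(
                "baseline hazard pieces must start at 0 with increasing start times"
            )

    def g(self, vc: np.ndarray) -> np.ndarray:
        """Planted log relative hazard of volume change (0 at the crossing)."""
        vc = np.asarray(vc, dtype=float)
        if self.vc_effect == "linear":
            return self.vc_log_hr_per_percent * (vc - self.crossing_vc)
        return np.zeros_like(vc)

    def calibrated_dc_mean(self) -> float:
        """DC mean placing the median VC (non-new-lesion mixture) at the crossing.

        Solved on a deterministic quantile grid of the DC and noise
        distributions, so the planted crossing is a property of the spec, not
        of any particular draw.
        """
        if self.dc_mean is not None:
            return float(self.dc_mean)
        m_dc, m_eps = 401, 41
        z_dc = stats.norm.ppf((np.arange(m_dc) + 0.5) / m_dc)
        z_eps = stats.norm.ppf((np.arange(m_eps) + 0.5) / m_eps)

        def median_gap(mu: float) -> float:
            dc = np.clip(mu + self.dc_sd * z_dc, -100.0, None)
            evc = ((1.0 + dc / 100.0) ** 3 - 1.0) * 100.0
            vc = np.clip(
                self.vc_slope * evc[:, None]
                + self.vc_intercept
                + self.vc_noise_sd * z_eps[None, :],
                -100.0,
                None,
            )
            p_cd = self.p_complete_disappearance
            frac_below = p_cd * 1.0 + (1 - p_cd) * float(np.mean(vc <= self.crossing_vc))
            return frac_below - 0.5

        return float(optimize.brentq(median_gap, -95.0, 30.0, xtol=1e-4))


def _piecewise_exponential(spec: CohortSpec, lp: np.ndarray, rng) -> np.ndarray:
    """Inverse-transform event times from a piecewise-constant baseline hazard."""
    pieces = list(spec.baseline_hazard)
    starts = np.array([s for s, _ in pieces] + [np.inf])
    rates = np.array([r for _, r in pieces])
    if np.any(rates <= 0):
        raise ValidationError("baseline hazard rates must be positive")
    targets = rng.exponential(1.0, size=len(lp)) / np.exp(lp)  # needed baseline cum. hazard
    times = np.empty(len(lp))
    cum_at_start = np.concatenate([[0.0], np.cumsum(rates[:-1] * np.diff(starts[:-1]))]) if len(
        pieces
    ) > 1 else np.array([0.0])
    for i, target in enumerate(targets):
        k = int(np.searchsorted(cum_at_start, target, side="right") - 1)
        k = min(k, len(rates) - 1)
        times[i] = starts[k] + (target - cum_at_start[k]) / rates[k]
    return times


def generate_cohort(spec: CohortSpec):
    """Draw one cohort; returns (records DataFrame, truth sidecar dict).

    The DataFrame follows the cohort CSV schema (id, measurements, flags,
    covariates, time_months, event); the sidecar carries the planted
    quantities a test can score against: true VC, true responder labels, the
    calibrated DC mean and the crossing.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    met = (rng.random(n) < spec.p_metastasis).astype(int)
    pvtt = (rng.random(n) < spec.p_pvtt).astype(int)
    subs = rng.choice(4, size=n, p=np.asarray(spec.subsequent_treatment_probs))

    new_lesion = rng.random(n) < spec.p_new_lesion
    complete_dis = (rng.random(n) < spec.p_complete_disappearance) & ~new_lesion

    d_bl = spec.d_bl_median_cm * np.exp(rng.normal(0.0, spec.d_bl_log_sd, n))
    dc_mean = spec.calibrated_dc_mean()
    dc = np.clip(rng.normal(dc_mean, spec.dc_sd, n), -100.0, None)
    evc = ((1.0 + dc / 100.0) ** 3 - 1.0) * 100.0
    vc = np.clip(
        spec.vc_slope * evc + spec.vc_intercept + rng.normal(0.0, spec.vc_noise_sd, n),
        -100.0,
        None,
    )
    dc[complete_dis] = -100.0
    vc[complete_dis] = -100.0
    d_up = d_bl * (1.0 + dc / 100.0)

    sphere_cm3 = np.pi / 6.0 * d_bl**3
    vtv_bl = spec.vtv_shape_factor * sphere_cm3 * np.exp(rng.normal(0.0, spec.vtv_bl_log_sd, n))
    vtv_up = vtv_bl * (1.0 + vc / 100.0)

    responder_true = (vc <= spec.crossing_vc) & ~new_lesion
    lp = (
        spec.beta_metastasis * met
        + spec.beta_pvtt * pvtt
        + spec.beta_subsequent * subs
    )
    if spec.vc_effect == "linear":
        lp = lp + spec.g(vc)
    elif spec.vc_effect == "responder":
        lp = lp + spec.beta_responder * responder_true.astype(float)

    t_event = _piecewise_exponential(spec, lp, rng)
    lo, hi = spec.censor_window_months
    t_admin = rng.uniform(lo, hi, n) if hi > lo else np.full(n, float(lo))
    t_drop = (
        rng.exponential(1.0 / spec.censoring_rate_per_month, n)
        if spec.censoring_rate_per_month > 0
        else np.full(n, np.inf)
    )
    t_cens = np.minimum(t_admin, t_drop)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-6)

    records = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "d_bl_cm": d_bl,
            "d_up_cm": d_up,
            "vtv_bl_cm3": vtv_bl,
            "vtv_up_cm3": vtv_up,
            "new_lesion": new_lesion.astype(int),
            "complete_disappearance": complete_dis.astype(int),
            "metastasis": met,
            "pvtt": pvtt,
            "subsequent_treatment": subs,
            "time_months": time,
            "event": event,
        }
    )
    truth = {
        "dc_mean": dc_mean,
        "crossing_vc": spec.crossing_vc,
        "vc_true": vc,
        "dc_true": dc,
        "responder_true": responder_true,
        "linear_predictor": lp,
        "betas": {
            "metastasis": spec.beta_metastasis,
            "pvtt": spec.beta_pvtt,
            "subsequent_treatment": spec.beta_subsequent,
            "responder": spec.beta_responder,
        },
        "vc_effect": spec.vc_effect,
    }
    return records, truth


def generate_paired_measurements(spec: CohortSpec, n: int | None = None) -> pd.DataFrame:
    """Baseline/follow-up diameter and volume table (no survival columns)."""
    if n is not None:
        spec = replace(spec, n=int(n))
    if spec.n < 3:
        raise ValidationError("need at least 3 measurement pairs")
    records, _ = generate_cohort(spec)
    return records[["d_bl_cm", "d_up_cm", "vtv_bl_cm3", "vtv_up_cm3"]].copy()
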