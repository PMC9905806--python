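"""Tumor response criteria: diameter (mRECIST) and volume (mqEASL) based.

All change quantities are percentages on the scale (followup - baseline) /
baseline x 100, bounded below by -100. The cube-law "expected volume change"
(EVC) maps a diameter change onto the volume change a uniformly shrinking
sphere would show; real lesions with irregular necrosis deviate from it,
which is why a volume-derived cutoff differs from the classical -65%.

mRECIST responder = complete or partial response on viable-tumor diameters.
mqEASL responder = viable-volume decrease at least as large as the cutoff
(default 57.0%) and no new lesion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar
from statsmodels.stats.inter_rater import cohens_kappa

from .exceptions import DegenerateDesignError, ValidationError

__all__ = [
    "MQEASL_CUTOFF_PERCENT",
    "LesionSetMeasurement",
    "ResponseAssessment",
    "AgreementResult",
    "percent_change",
    "expected_volume_change",
    "classify_mrecist",
    "classify_mqeasl",
    "assess_response",
    "agreement",
    "fit_evc_vc_line",
    "annotate_cohort",
]

#: Volumetric responder cutoff (percent change); a decrease of at least this
#: magnitude, absent new lesions, is a volumetric response.
MQEASL_CUTOFF_PERCENT = -57.0

RESPONDER_CATEGORIES = frozenset({"CR", "PR"})


@dataclass
class LesionSetMeasurement:
    """One timepoint's diameter sum (cm) and viable tumor volume (cm^3)."""

    timepoint: str  # "baseline" | "followup"
    d_sum_cm: float
    vtv_cm3: float
    new_lesion: bool = False
    complete_disappearance: bool = False

    def __post_init__(self):
        if self.timepoint not in ("baseline", "followup"):
            raise ValidationError("timepoint must be 'baseline' or 'followup'")
        if self.d_sum_cm < 0 or self.vtv_cm3 < 0:
            raise ValidationError("diameter sum and volume must be non-negative")
        if self.complete_disappearance and (self.d_sum_cm != 0 or self.vtv_cm3 != 0):
            raise ValidationError(
                "complete disappearance requires zero residual diameter and volume"
            )


@dataclass
class ResponseAssessment:
    dc_percent: float
    vc_percent: float
    evc_percent: float
    mrecist_category: str
    mrecist_responder: bool
    mqeasl_responder: bool


@dataclass
class AgreementResult:
    """Agreement between the diameter- and volume-based responder calls."""

    table: np.ndarray  # 2x2: rows mRECIST (no/yes), cols mqEASL (no/yes)
    kappa: float
    kappa_ci95: tuple[float, float]
    mcnemar_p: float
    qualitative: str
    degenerate: bool = False


def percent_change(baseline: float, followup: float) -> float:
    """(followup - baseline) / baseline x 100; baseline must be positive."""
    if baseline <= 0:
        raise ValidationError("percent change is undefined for baseline <= 0")
    if followup < 0:
        raise ValidationError("followup measurement must be non-negative")
    return (followup - baseline) / baseline * 100.0


def expected_volume_change(dc_percent: float) -> float:
    """Cube-law volume change implied by a diameter change of dc_percent.

    EVC = ((1 + DC/100)^3 - 1) x 100.  A -30% diameter change maps to -65.7%.
    """
    if dc_percent < -100:
        raise ValidationError("diameter change below -100% is impossible")
    return ((1.0 + dc_percent / 100.0) ** 3 - 1.0) * 100.0


def classify_mrecist(
    dc_percent: float, new_lesion: bool = False, complete_disappearance: bool = False
) -> str:
    """mRECIST category from the viable-diameter change against baseline.

    Precedence: new lesion forces PD even with disappearing targets; then CR
    (no residual target enhancement); then PD at >= +20%; then PR at <= -30%;
    otherwise SD.
    """
    if new_lesion:
        return "PD"
    if complete_disappearance:
        return "CR"
    if dc_percent >= 20.0:
        return "PD"
    if dc_percent <= -30.0:
        return "PR"
    return "SD"


def classify_mqeasl(
    vc_percent: float,
    new_lesion: bool = False,
    cutoff_percent: float = MQEASL_CUTOFF_PERCENT,
) -> bool:
    """Volumetric responder call: VC at or below the cutoff and no new lesion."""
    if vc_percent < -100:
        raise ValidationError("volume change below -100% is impossible")
    return (vc_percent <= cutoff_percent) and not new_lesion


def assess_response(
    baseline: LesionSetMeasurement,
    followup: LesionSetMeasurement,
    cutoff_percent: float = MQEASL_CUTOFF_PERCENT,
) -> ResponseAssessment:
    """Full per-patient assessment from a baseline/follow-up measurement pair."""
    if baseline.timepoint != "baseline" or followup.timepoint != "followup":
        raise ValidationError("expected one baseline and one followup measurement")
    if followup.complete_disappearance:
        dc = vc = -100.0
    else:
        dc = percent_change(baseline.d_sum_cm, followup.d_sum_cm)
        vc = percent_change(baseline.vtv_cm3, followup.vtv_cm3)
    cat = classify_mrecist(dc, followup.new_lesion, followup.complete_disappearance)
    return ResponseAssessment(
        dc_percent=dc,
        vc_percent=vc,
        evc_percent=expected_volume_change(dc),
        mrecist_category=cat,
        mrecist_responder=cat in RESPONDER_CATEGORIES,
        mqeasl_responder=classify_mqeasl(vc, followup.new_lesion, cutoff_percent),
    )


def _kappa_band(kappa: float) -> str:
    if kappa < 0.4:
        return "poor"
    if kappa <= 0.75:
        return "moderate"
    return "excellent"


def agreement(paired_labels) -> AgreementResult:
    """Cross-tabulate (mRECIST responder, mqEASL responder) pairs.

    Cohen's kappa with an asymptotic 95% CI; McNemar on the discordant cells
    (exact binomial when fewer than 25 discordant pairs, chi-square without
    continuity correction otherwise).
    """
    labels = [(bool(a), bool(b)) for a, b in paired_labels]
    if not labels:
        raise ValidationError("at least one labelled pair is required")
    table = np.zeros((2, 2), dtype=int)
    for a, b in labels:
        table[int(a), int(b)] += 1
    n = table.sum()
    marg_a = table.sum(axis=1) / n
    marg_b = table.sum(axis=0) / n
    pe = float(marg_a @ marg_b)
    if pe >= 1.0 - 1e-12:
        return AgreementResult(
            table=table,
            kappa=float("nan"),
            kappa_ci95=(float("nan"), float("nan")),
            mcnemar_p=1.0,
            qualitative="degenerate",
            degenerate=True,
        )
    kres = cohens_kappa(table, return_results=True)
    kappa = float(kres.kappa)
    ci = (float(kres.kappa_low), float(kres.kappa_upp))
    discordant = int(table[0, 1] + table[1, 0])
    mres = sm_mcnemar(table, exact=discordant < 25, correction=False)
    return AgreementResult(
        table=table,
        kappa=kappa,
        kappa_ci95=ci,
        mcnemar_p=float(mres.pvalue),
        qualitative=_kappa_band(kappa),
    )


def fit_evc_vc_line(pairs) -> tuple[float, float]:
    """OLS fit of actual volume change on the cube-law expected change.

    Returns (slope, intercept) of VC = slope * EVC + intercept.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValidationError("pairs must be (evc_percent, vc_percent) tuples")
    if arr.shape[0] < 2:
        raise ValidationError("at least two points are required")
    evc, vc = arr[:, 0], arr[:, 1]
    if np.ptp(evc) == 0:
        raise DegenerateDesignError("all EVC values are equal; slope is unidentifiable")
    res = stats.linregress(evc, vc)
    return float(res.slope), float(res.intercept)


COHORT_REQUIRED_COLUMNS = [
    "id",
    "d_bl_cm",
    "d_up_cm",
    "vtv_bl_cm3",
    "vtv_up_cm3",
    "new_lesion",
    "complete_disappearance",
    "metastasis",
    "pvtt",
    "subsequent_treatment",
    "time_months",
    "event",
]


def validate_cohort(df: pd.DataFrame) -> None:
    missing = [c for c in COHORT_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort table lacks columns: {missing}")
    if len(df) == 0:
        raise ValidationError("cohort table is empty")
    bad = df.index[(df["time_months"] <= 0) | ~df["event"].isin((0, 1))]
    if len(bad):
        raise ValidationError(f"invalid time/event values in rows: {list(bad[:10])}")


def annotate_cohort(
    df: pd.DataFrame, cutoff_percent: float = MQEASL_CUTOFF_PERCENT
) -> pd.DataFrame:
    """Append response columns (DC/VC/EVC, categories, responder flags) to a cohort.

    Expects the cohort CSV schema; returns a copy with the derived columns.
    """
    validate_cohort(df)
    out = df.copy()
    rows = []
    for r in df.itertuples():
        bl = LesionSetMeasurement("baseline", r.d_bl_cm, r.vtv_bl_cm3)
        up = LesionSetMeasurement(
            "followup",
            r.d_up_cm,
            r.vtv_up_cm3,
            new_lesion=bool(r.new_lesion),
            complete_disappearance=bool(r.complete_disappearance),
        )
        a = assess_response(bl, up, cutoff_percent=cutoff_percent)
        rows.append(
            (
                a.dc_percent,
                a.vc_percent,
                a.evc_percent,
                a.mrecist_category,
                a.mrecist_responder,
                a.mqeasl_responder,
            )
        )
    (
        out["dc_percent"],
        out["vc_percent"],
        out["evc_percent"],
        out["mrecist_category"],
        out["mrecist_responder"],
        out["mqeasl_responder"],
    ) = map(list, zip(*rows))
    return out
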