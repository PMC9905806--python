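"""Survival comparison of diameter- vs volume-based response markers.

Provides the downstream statistics of the analysis: cohort splitting,
Kaplan-Meier medians and log-rank comparisons of responders vs
non-responders, multivariable Cox models combining pretreatment covariates
with a response marker (Model 1 = mRECIST responder, Model 2 = mqEASL
responder), and model discrimination/calibration: Harrell's C with a
U-statistic standard error, time-dependent AUROC (IPCW cumulative cases /
dynamic controls), and calibration tables against a Breslow baseline.

Subsequent treatment is coded as a single ordinal 0-3 term (none /
locoregional / systemic / combined); metastasis, PVTT and responder are
binary, so a fitted model is fully described by four named coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import median_survival_times
from scipy import stats

from .exceptions import FitError, ValidationError

__all__ = [
    "split_cohort",
    "KMEstimate",
    "km_median",
    "logrank",
    "KMComparison",
    "compare_responder_survival",
    "CoxModelSpec",
    "MODEL1_PUBLISHED",
    "MODEL2_PUBLISHED",
    "ResponseCoxModel",
    "ResponseCoxResults",
    "fit_cox_multivariate",
    "linear_predictor",
    "harrells_c",
    "td_auroc",
    "breslow_cumulative_hazard",
    "calibration_table",
    "univariate_screen",
]

DEFAULT_COVARIATES = ("metastasis", "pvtt", "subsequent_treatment")
DEFAULT_HORIZONS_MONTHS = (6.0, 12.0, 24.0)


# ---------------------------------------------------------------------------
# Cohort splitting


def split_cohort(records: pd.DataFrame, ratio: float = 0.7, seed=None):
    """Random 7:3-style partition into training and validation cohorts.

    The training size is round(n * ratio); the partition is reproducible
    given the seed, disjoint, and exhaustive.
    """
    if not 0 < ratio < 1:
        raise ValidationError("split ratio must be in (0, 1)")
    n = len(records)
    if n < 10:
        raise ValidationError("cohort too small to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(n * ratio))
    train = records.iloc[np.sort(perm[:n_train])].copy()
    valid = records.iloc[np.sort(perm[n_train:])].copy()
    return train, valid


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank


@dataclass
class KMEstimate:
    median_months: float  # nan if the curve never falls to 0.5
    ci95: tuple[float, float]  # nan bounds where undefined (open interval)
    n: int
    n_events: int


def _nan_if_inf(x: float) -> float:
    return float("nan") if np.isinf(x) else float(x)


def km_median(times, events) -> KMEstimate:
    """Kaplan-Meier median survival with a log-log (Brookmeyer-Crowley) CI."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() < 1:
        raise ValidationError("at least one event is required for a KM median")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    med = kmf.median_survival_time_
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    return KMEstimate(
        median_months=_nan_if_inf(med),
        ci95=(_nan_if_inf(lo), _nan_if_inf(hi)),
        n=len(times),
        n_events=int(events.sum()),
    )


def logrank(times_a, events_a, times_b, events_b):
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    ta, tb = np.asarray(times_a, float), np.asarray(times_b, float)
    if len(ta) == 0 or len(tb) == 0:
        raise ValidationError("both groups must be non-empty")
    res = logrank_test(ta, tb, event_observed_A=events_a, event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class KMComparison:
    """Responder vs non-responder survival under one response marker."""

    marker: str
    responder: KMEstimate
    non_responder: KMEstimate
    logrank_statistic: float
    logrank_p: float


def compare_responder_survival(records: pd.DataFrame, marker: str) -> KMComparison:
    col = f"{marker}_responder"
    if col not in records.columns:
        raise ValidationError(f"cohort lacks column {col!r}")
    resp = records[records[col].astype(bool)]
    nonresp = records[~records[col].astype(bool)]
    if len(resp) == 0 or len(nonresp) == 0:
        raise ValidationError(f"one {marker} responder group is empty")
    stat, p = logrank(
        resp["time_months"], resp["event"], nonresp["time_months"], nonresp["event"]
    )
    return KMComparison(
        marker=marker,
        responder=km_median(resp["time_months"], resp["event"]),
        non_responder=km_median(nonresp["time_months"], nonresp["event"]),
        logrank_statistic=stat,
        logrank_p=p,
    )


# ---------------------------------------------------------------------------
# Cox model specification and fitting


@dataclass
class CoxModelSpec:
    """Named coefficients defining a linear predictor LP = sum(coef * value)."""

    terms: list[tuple[str, str, float]]  # (covariate, coding {binary, ordinal}, coefficient)
    response_marker: str | None = None

    def __post_init__(self):
        for name, coding, coef in self.terms:
            if coding not in ("binary", "ordinal"):
                raise ValidationError(f"unknown coding {coding!r} for {name!r}")
            if not np.isfinite(coef):
                raise ValidationError(f"non-finite coefficient for {name!r}")

    @property
    def coefficients(self) -> dict[str, float]:
        return {name: coef for name, _, coef in self.terms}

    def linear_predictor(self, patient) -> float:
        """LP for one patient (mapping/Series) from the named coefficients."""
        lp = 0.0
        for name, _, coef in self.terms:
            if name not in patient:
                raise ValidationError(f"patient record lacks covariate {name!r}")
            lp += coef * float(patient[name])
        return lp

    def linear_predictor_frame(self, records: pd.DataFrame) -> np.ndarray:
        missing = [name for name, _, _ in self.terms if name not in records.columns]
        if missing:
            raise ValidationError(f"records lack covariates {missing}")
        X = records[[name for name, _, _ in self.terms]].to_numpy(dtype=float)
        beta = np.array([coef for _, _, coef in self.terms])
        return X @ beta


def linear_predictor(spec: CoxModelSpec, patient) -> float:
    return spec.linear_predictor(patient)


#: The published multivariable models (training-cohort fits): pretreatment
#: covariates plus the response marker of each criterion.
MODEL1_PUBLISHED = CoxModelSpec(
    terms=[
        ("metastasis", "binary", 1.68),
        ("pvtt", "binary", 1.43),
        ("subsequent_treatment", "ordinal", -0.47),
        ("responder", "binary", -1.08),
    ],
    response_marker="mrecist",
)
MODEL2_PUBLISHED = CoxModelSpec(
    terms=[
        ("metastasis", "binary", 1.88),
        ("pvtt", "binary", 0.92),
        ("subsequent_treatment", "ordinal", -0.36),
        ("responder", "binary", -1.41),
    ],
    response_marker="mqeasl",
)


def _coding_for(name: str, values: np.ndarray) -> str:
    if name == "subsequent_treatment":
        return "ordinal"
    return "binary" if set(np.unique(values)) <= {0, 1} else "ordinal"


class ResponseCoxModel:
    """Multivariable Cox model of overall survival with a response marker.

    Parameters
    ----------
    data : annotated cohort frame (schema of :func:`mqeasl.response.annotate_cohort`).
    response_marker : "mrecist", "mqeasl" or None. When given, the matching
        ``<marker>_responder`` column is entered as a binary ``responder`` term.
    covariates : pretreatment covariate columns; ``subsequent_treatment`` is
        coded as a single ordinal 0-3 term.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        response_marker: str | None = "mqeasl",
        covariates=DEFAULT_COVARIATES,
        duration_col: str = "time_months",
        event_col: str = "event",
    ):
        cov = list(covariates)
        df = data.copy()
        if response_marker is not None:
            col = f"{response_marker}_responder"
            if col not in df.columns:
                raise ValidationError(f"cohort lacks column {col!r}")
            df["responder"] = df[col].astype(int)
            cov.append("responder")
        missing = [c for c in cov + [duration_col, event_col] if c not in df.columns]
        if missing:
            raise ValidationError(f"cohort lacks columns {missing}")
        self.data = df
        self.covariates = cov
        self.response_marker = response_marker
        self.duration_col = duration_col
        self.event_col = event_col

    @classmethod
    def from_dataframe(cls, data, **kwargs) -> "ResponseCoxModel":
        return cls(data, **kwargs)

    def fit(self) -> "ResponseCoxResults":
        df = self.data
        n_events = int(df[self.event_col].sum())
        if n_events < 1:
            raise FitError("cannot fit a Cox model with no events")
        if n_events < 10 * len(self.covariates):
            warnings.warn(
                f"only {n_events} events for {len(self.covariates)} covariates; "
                "fewer than 10 events per variable",
                stacklevel=2,
            )
        cph = CoxPHFitter()
        cols = self.covariates + [self.duration_col, self.event_col]
        try:
            cph.fit(df[cols], duration_col=self.duration_col, event_col=self.event_col)
        except Exception as exc:
            raise FitError(f"Cox fit failed (separation or non-convergence?): {exc}") from exc
        terms = [
            (name, _coding_for(name, df[name].to_numpy()), float(cph.params_[name]))
            for name in self.covariates
        ]
        spec = CoxModelSpec(terms=terms, response_marker=self.response_marker)
        lp_train = spec.linear_predictor_frame(df)
        base_t, base_H = breslow_cumulative_hazard(
            lp_train, df[self.duration_col].to_numpy(float), df[self.event_col].to_numpy(int)
        )
        return ResponseCoxResults(
            model=self,
            spec=spec,
            params=cph.params_.copy(),
            standard_errors=cph.standard_errors_.copy(),
            covariance=cph.variance_matrix_.to_numpy(),
            log_likelihood=float(cph.log_likelihood_),
            baseline_times=base_t,
            baseline_cumhaz=base_H,
            n=len(df),
            n_events=n_events,
        )


@dataclass
class ResponseCoxResults:
    """Fitted model: coefficients, uncertainty, and performance measures."""

    model: ResponseCoxModel = field(repr=False)
    spec: CoxModelSpec
    params: pd.Series
    standard_errors: pd.Series
    covariance: np.ndarray
    log_likelihood: float
    baseline_times: np.ndarray
    baseline_cumhaz: np.ndarray
    n: int
    n_events: int

    def linear_predictor(self, records: pd.DataFrame | None = None) -> np.ndarray:
        if records is None:
            records = self.model.data
        marker = self.model.response_marker
        if marker is not None and "responder" not in records.columns:
            records = records.assign(responder=records[f"{marker}_responder"].astype(int))
        return self.spec.linear_predictor_frame(records)

    def predicted_survival(self, records: pd.DataFrame, horizon: float) -> np.ndarray:
        """S(horizon | x) = exp(-H0(horizon) * exp(LP)) with a Breslow baseline."""
        H0 = _step_interp(self.baseline_times, self.baseline_cumhaz, horizon)
        return np.exp(-H0 * np.exp(self.linear_predictor(records)))

    def concordance(self, records: pd.DataFrame | None = None) -> tuple[float, float]:
        if records is None:
            records = self.model.data
        return harrells_c(
            self.linear_predictor(records),
            records[self.model.duration_col],
            records[self.model.event_col],
        )

    def td_auroc(self, horizon: float, records: pd.DataFrame | None = None, **kwargs):
        if records is None:
            records = self.model.data
        train = self.model.data
        return td_auroc(
            self.linear_predictor(records),
            records[self.model.duration_col],
            records[self.model.event_col],
            horizon,
            train=(
                self.linear_predictor(train),
                train[self.model.duration_col],
                train[self.model.event_col],
            ),
            **kwargs,
        )

    def calibration_table(
        self, records: pd.DataFrame | None = None, horizon: float = 12.0, n_groups: int = 3
    ) -> pd.DataFrame:
        if records is None:
            records = self.model.data
        pred = self.predicted_survival(records, horizon)
        return calibration_table(
            pred,
            records[self.model.duration_col].to_numpy(float),
            records[self.model.event_col].to_numpy(int),
            horizon,
            n_groups=n_groups,
        )

    def summary(self) -> pd.DataFrame:
        z = self.params / self.standard_errors
        p = 2 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {
                "coef": self.params,
                "se(coef)": self.standard_errors,
                "HR": np.exp(self.params),
                "z": z,
                "p": p,
            }
        )

    def performance_report(
        self, records: pd.DataFrame | None = None, horizons=DEFAULT_HORIZONS_MONTHS, **auc_kwargs
    ) -> dict:
        """Bundle C-index, per-horizon AUROC and calibration for one cohort."""
        if records is None:
            records = self.model.data
        c, c_se = self.concordance(records)
        report = {
            "response_marker": self.model.response_marker,
            "n": int(len(records)),
            "c_index": c,
            "c_index_se": c_se,
            "auroc": {},
            "calibration": {},
        }
        for h in horizons:
            try:
                auc, lo, hi = self.td_auroc(h, records, **auc_kwargs)
                report["auroc"][h] = {"auc": auc, "ci95": [lo, hi]}
            except ValidationError as exc:
                report["auroc"][h] = {"error": str(exc)}
            tab = self.calibration_table(records, horizon=h)
            report["calibration"][h] = tab.to_dict(orient="records")
        return report


def fit_cox_multivariate(
    records: pd.DataFrame,
    covariates,
    duration_col: str = "time_months",
    event_col: str = "event",
) -> CoxModelSpec:
    """Plain multivariable Cox fit over the given covariate columns."""
    model = ResponseCoxModel(
        records,
        response_marker=None,
        covariates=covariates,
        duration_col=duration_col,
        event_col=event_col,
    )
    return model.fit().spec


def univariate_screen(
    records: pd.DataFrame,
    candidates,
    alpha: float = 0.05,
    duration_col: str = "time_months",
    event_col: str = "event",
) -> pd.DataFrame:
    """Single-covariate Cox screens; covariates with p < alpha are selected."""
    rows = []
    for name in candidates:
        cph = CoxPHFitter()
        cph.fit(
            records[[name, duration_col, event_col]],
            duration_col=duration_col,
            event_col=event_col,
        )
        p = float(cph.summary.loc[name, "p"])
        rows.append({"covariate": name, "coef": float(cph.params_[name]), "p": p})
    out = pd.DataFrame(rows).set_index("covariate")
    out["selected"] = out["p"] < alpha
    return out


# ---------------------------------------------------------------------------
# Discrimination


def harrells_c(lp, times, events) -> tuple[float, float]:
    """Harrell's concordance index with a U-statistic standard error.

    A pair is usable when the ordering of the true survival times is known:
    the earlier time is an event, or the times are tied with exactly one
    event (the event subject died first). Higher linear predictor predicting
    shorter survival is concordant; ties in the predictor score 1/2. The SE
    follows the delta-method variance of the ratio of pair sums.
    """
    lp = np.asarray(lp, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(bool)
    if not (len(lp) == len(t) == len(e)):
        raise ValidationError("lp, times and events must have equal length")
    dt = t[:, None] - t[None, :]
    usable = ((dt < 0) & e[:, None]) | ((dt == 0) & e[:, None] & ~e[None, :])
    m_total = int(usable.sum())
    if m_total == 0:
        raise ValidationError("no usable (comparable) pairs")
    dl = lp[:, None] - lp[None, :]
    score = np.where(dl > 0, 1.0, np.where(dl == 0, 0.5, 0.0))
    c = float((usable * score).sum() / m_total)
    # per-subject pair sums, counting each subject's role on either side
    c_i = (usable * score).sum(axis=1) + (usable * score).sum(axis=0)
    m_i = usable.sum(axis=1) + usable.sum(axis=0)
    var = 4.0 * float(((c_i - c * m_i) ** 2).sum()) / m_total**2
    return c, float(np.sqrt(var))


def _naive_auc(case_scores: np.ndarray, control_scores: np.ndarray) -> float:
    n1, n0 = len(case_scores), len(control_scores)
    diff = case_scores[:, None] - control_scores[None, :]
    wins = (diff > 0).sum() + 0.5 * (diff == 0).sum()
    return float(wins / (n1 * n0))


def td_auroc(
    lp,
    times,
    events,
    horizon: float,
    train=None,
    method: str = "ipcw",
    n_bootstrap: int = 500,
    seed=0,
    alpha: float = 0.05,
):
    """Time-dependent AUROC at a horizon: cumulative cases / dynamic controls.

    Cases die by the horizon; controls survive past it. The default estimator
    weights by the inverse probability of censoring (censoring distribution
    estimated on the training data, or on the evaluated data itself when no
    training tuple is supplied); ``method="naive"`` counts observed cases and
    controls directly. The CI is a seeded bootstrap percentile interval.
    """
    lp = np.asarray(lp, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(bool)
    if not ((t <= horizon) & e).any():
        raise ValidationError("no events before the horizon")
    if not (t > horizon).any():
        raise ValidationError("no subjects at risk beyond the horizon")

    def point_estimate(lp_, t_, e_) -> float:
        if method == "naive":
            return _naive_auc(lp_[(t_ <= horizon) & e_], lp_[t_ > horizon])
        from sksurv.metrics import cumulative_dynamic_auc
        from sksurv.util import Surv

        if train is None:
            y_train = Surv.from_arrays(e_, t_)
        else:
            lp_tr, t_tr, e_tr = train
            y_train = Surv.from_arrays(np.asarray(e_tr).astype(bool), np.asarray(t_tr, float))
        y_test = Surv.from_arrays(e_, t_)
        auc, _ = cumulative_dynamic_auc(y_train, y_test, lp_, [horizon])
        return float(auc[0])

    auc = point_estimate(lp, t, e)
    if n_bootstrap and n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        boots = []
        n = len(lp)
        for _ in range(n_bootstrap):
            idx = rng.integers(0, n, n)
            tb, eb, lb = t[idx], e[idx], lp[idx]
            if not ((tb <= horizon) & eb).any() or not (tb > horizon).any():
                continue
            try:
                boots.append(point_estimate(lb, tb, eb))
            except Exception:
                continue
        if boots:
            lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
        else:
            lo = hi = float("nan")
    else:
        lo = hi = float("nan")
    return auc, float(lo), float(hi)


# ---------------------------------------------------------------------------
# Calibration


def breslow_cumulative_hazard(lp, times, events):
    """Breslow estimate of the baseline cumulative hazard H0(t) at LP = 0.

    Returns (event_times, H0) as a right-continuous step function.
    """
    lp = np.asarray(lp, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(bool)
    risk = np.exp(lp)
    uniq = np.unique(t[e])
    increments = []
    for tk in uniq:
        d = int((e & (t == tk)).sum())
        denom = risk[t >= tk].sum()
        increments.append(d / denom)
    return uniq, np.cumsum(increments) if len(uniq) else np.array([])


def _step_interp(step_times: np.ndarray, step_values: np.ndarray, x: float) -> float:
    idx = np.searchsorted(step_times, x, side="right") - 1
    return 0.0 if idx < 0 else float(step_values[idx])


def calibration_table(
    predicted_survival, times, events, horizon: float, n_groups: int = 3
) -> pd.DataFrame:
    """Predicted vs KM-observed survival at a horizon by predicted-risk group.

    Patients are grouped by quantiles of predicted survival (a constant
    predictor collapses to one group). Groups whose follow-up does not reach
    the horizon are flagged rather than dropped.
    """
    pred = np.asarray(predicted_survival, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(int)
    if np.ptp(pred) == 0:  # constant predictor: one effective group
        labels = np.zeros(len(pred), dtype=int)
    else:
        labels = pd.qcut(pred, q=n_groups, labels=False, duplicates="drop")
    rows = []
    for g in sorted(pd.unique(labels)):
        sel = labels == g
        kmf = KaplanMeierFitter()
        kmf.fit(t[sel], e[sel])
        observed = float(kmf.predict(horizon))
        ci = kmf.confidence_interval_survival_function_
        at_or_before = ci.index[ci.index <= horizon]
        if len(at_or_before):
            last = ci.loc[at_or_before[-1]]
            obs_lo, obs_hi = float(last.iloc[0]), float(last.iloc[1])
        else:
            obs_lo, obs_hi = float("nan"), float("nan")
        rows.append(
            {
                "group": int(g),
                "n": int(sel.sum()),
                "predicted_survival": float(pred[sel].mean()),
                "observed_survival": observed,
                "observed_ci_low": obs_lo,
                "observed_ci_high": obs_hi,
                "no_subjects_at_risk": bool(t[sel].max() < horizon),
            }
        )
    return pd.DataFrame(rows)
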