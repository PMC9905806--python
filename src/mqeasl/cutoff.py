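"""Data-driven volumetric response cutoff via a spline Cox hazard model.

The association between viable-volume change (VC, percent) and the hazard of
death is modelled with a Cox proportional-hazards fit on a four-knot
restricted (natural) cubic spline basis of VC. The hazard-ratio curve is
drawn relative to a reference VC (default: the cohort median), and the VC at
which the curve crosses HR = 1 is adopted as the responder cutoff.

Patients with new lesions are progressive disease by definition and are
excluded from cutoff derivation (they stay in every downstream analysis as
non-responders).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy.optimize import brentq

from .exceptions import FitError, NoCrossingError, ValidationError

__all__ = [
    "rcs_basis",
    "default_knots",
    "VolumeCutoffCox",
    "SplineHazardFit",
    "CutoffResult",
    "fit_vc_hazard_spline",
    "find_unit_hr_crossing",
]

DEFAULT_KNOT_QUANTILES = (0.05, 0.35, 0.65, 0.95)


def rcs_basis(x, knots) -> np.ndarray:
    """Restricted cubic spline basis (truncated-power form, Harrell scaling).

    For k knots t_1 < ... < t_k the basis has k-1 columns: the identity plus
    k-2 nonlinear terms

        B_j(x) = [ (x-t_j)_+^3
                   - (x-t_{k-1})_+^3 (t_k-t_j)/(t_k-t_{k-1})
                   + (x-t_k)_+^3 (t_{k-1}-t_j)/(t_k-t_{k-1}) ] / (t_k-t_1)^2

    which are zero below t_1 and exactly linear above t_k, so the fitted
    curve is linear beyond the boundary knots.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    t = np.asarray(knots, dtype=float)
    if t.ndim != 1 or len(t) < 3:
        raise ValidationError("at least three knots are required")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("knots must be strictly increasing")
    k = len(t)
    norm = (t[-1] - t[0]) ** 2
    cols = [x]
    plus3 = lambda u: np.maximum(u, 0.0) ** 3
    for j in range(k - 2):
        term = (
            plus3(x - t[j])
            - plus3(x - t[k - 2]) * (t[k - 1] - t[j]) / (t[k - 1] - t[k - 2])
            + plus3(x - t[k - 1]) * (t[k - 2] - t[j]) / (t[k - 1] - t[k - 2])
        ) / norm
        cols.append(term)
    return np.column_stack(cols)


def default_knots(vc_values, quantiles=DEFAULT_KNOT_QUANTILES) -> np.ndarray:
    """Knot locations at the standard quantiles of the observed VC values."""
    vals = np.asarray(vc_values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(np.unique(vals)) < 20:
        raise ValidationError("need at least 20 distinct values to place knots")
    knots = np.quantile(vals, quantiles)
    if np.any(np.diff(knots) <= 0):
        raise ValidationError("knot quantiles collapse; distribution too discrete")
    return knots


@dataclass
class SplineHazardFit:
    """Fitted spline Cox model of the VC -> log relative hazard curve."""

    knots: np.ndarray
    coefficients: np.ndarray  # aligned with the retained basis columns
    covariance: np.ndarray
    reference_value: float
    basis_columns: np.ndarray  # indices of retained (non-collinear) columns
    vc_range: tuple[float, float]
    n_used: int
    n_events: int
    vc_values: np.ndarray | None = field(default=None, repr=False)

    def _design(self, x) -> np.ndarray:
        return rcs_basis(x, self.knots)[:, self.basis_columns]

    def log_hazard_ratio(self, x) -> np.ndarray:
        """Log HR of VC=x relative to the reference value."""
        d = self._design(x) - self._design([self.reference_value])
        return d @ self.coefficients

    def hazard_ratio(self, x) -> np.ndarray:
        return np.exp(self.log_hazard_ratio(x))

    def hazard_ratio_ci(self, x, alpha: float = 0.05):
        """Pointwise delta-method CI for the HR curve."""
        from scipy.stats import norm

        d = self._design(x) - self._design([self.reference_value])
        log_hr = d @ self.coefficients
        se = np.sqrt(np.einsum("ij,jk,ik->i", d, self.covariance, d))
        z = norm.ppf(1 - alpha / 2)
        return np.exp(log_hr), np.exp(log_hr - z * se), np.exp(log_hr + z * se)

    def curve(self, grid=None, alpha: float = 0.05) -> pd.DataFrame:
        if grid is None:
            grid = np.arange(self.vc_range[0], self.vc_range[1] + 1e-9, 0.5)
        hr, lo, hi = self.hazard_ratio_ci(grid, alpha)
        return pd.DataFrame(
            {"vc_percent": grid, "hr": hr, "hr_ci_low": lo, "hr_ci_high": hi}
        )


@dataclass
class CutoffResult:
    """The HR=1 crossing chosen as the volumetric response cutoff."""

    cutoff_percent: float
    roots: list[float]
    curve_samples: pd.DataFrame
    n_used: int
    fit: SplineHazardFit = field(repr=False, default=None)

    def to_report(self) -> dict:
        return {
            "cutoff_percent": self.cutoff_percent,
            "all_roots_percent": list(self.roots),
            "knots": list(map(float, self.fit.knots)) if self.fit is not None else None,
            "coefficients": list(map(float, self.fit.coefficients))
            if self.fit is not None
            else None,
            "reference_value": self.fit.reference_value if self.fit is not None else None,
            "n_used": self.n_used,
            "n_events": self.fit.n_events if self.fit is not None else None,
        }

    def save_report(self, json_path, curve_csv_path=None) -> None:
        with open(json_path, "w") as fh:
            json.dump(self.to_report(), fh, indent=2)
        if curve_csv_path is not None:
            self.curve_samples.to_csv(curve_csv_path, index=False)


def _independent_columns(mat: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Indices of a maximal set of linearly independent (centered) columns."""
    centered = mat - mat.mean(axis=0)
    keep: list[int] = []
    for j in range(centered.shape[1]):
        cand = centered[:, keep + [j]]
        if np.linalg.matrix_rank(cand, tol=tol * max(1.0, np.abs(cand).max())) == len(keep) + 1:
            keep.append(j)
    if not keep:
        raise ValidationError("VC has no variation; spline fit impossible")
    return np.asarray(keep, dtype=int)


class VolumeCutoffCox:
    """Cox model of death hazard as a smooth function of volume change.

    Parameters
    ----------
    data : DataFrame with columns ``vc_percent``, ``time_months``, ``event``
        and optionally ``new_lesion`` (rows with a new lesion are excluded
        from the fit).
    knots : optional explicit knot locations; default Harrell quantiles
        (0.05, 0.35, 0.65, 0.95) of the analysed VC values.
    reference_value : VC at which the hazard ratio is anchored to 1;
        default the median VC of the analysed records.
    """

    def __init__(self, data: pd.DataFrame, knots=None, reference_value=None,
                 exclude_new_lesions: bool = True, ridge: float = 1e-4):
        required = {"vc_percent", "time_months", "event"}
        missing = required - set(data.columns)
        if missing:
            raise ValidationError(f"missing columns: {sorted(missing)}")
        df = data.copy()
        if exclude_new_lesions and "new_lesion" in df.columns:
            df = df.loc[~df["new_lesion"].astype(bool)]
        if len(df) == 0:
            raise ValidationError("no records left after exclusions")
        if (df["time_months"] <= 0).any():
            raise ValidationError("all survival times must be positive")
        self.data = df.reset_index(drop=True)
        self.knots = None if knots is None else np.asarray(knots, dtype=float)
        self.reference_value = reference_value
        # tiny ridge on the standardized basis: the nonlinear terms can be
        # near-collinear when knots crowd together, which stalls plain Newton
        self.ridge = float(ridge)

    def fit(self) -> SplineHazardFit:
        df = self.data
        if int(df["event"].sum()) < 1:
            raise FitError("cannot fit a Cox model with no events")
        vc = df["vc_percent"].to_numpy(dtype=float)
        knots = self.knots if self.knots is not None else default_knots(vc)
        basis = rcs_basis(vc, knots)
        cols = _independent_columns(basis)
        names = [f"rcs{j}" for j in cols]
        X = basis[:, cols]
        scale = X.std(axis=0)  # condition the solver; undone on the way out
        scale[scale == 0] = 1.0
        fit_df = pd.DataFrame(X / scale, columns=names)
        fit_df["time_months"] = df["time_months"].to_numpy(dtype=float)
        fit_df["event"] = df["event"].to_numpy(dtype=int)
        cph = CoxPHFitter(penalizer=self.ridge, l1_ratio=0.0)
        try:
            cph.fit(fit_df, duration_col="time_months", event_col="event")
        except Exception as exc:  # pragma: no cover - converted diagnostics
            raise FitError(f"spline Cox fit failed: {exc}") from exc
        ref = (
            float(np.median(vc)) if self.reference_value is None else float(self.reference_value)
        )
        return SplineHazardFit(
            knots=knots,
            coefficients=cph.params_.to_numpy() / scale,
            covariance=cph.variance_matrix_.to_numpy() / np.outer(scale, scale),
            reference_value=ref,
            basis_columns=cols,
            vc_range=(float(vc.min()), float(vc.max())),
            n_used=len(df),
            n_events=int(df["event"].sum()),
            vc_values=vc,
        )


def fit_vc_hazard_spline(records: pd.DataFrame, knots=None, reference_value=None) -> SplineHazardFit:
    """Functional wrapper around :class:`VolumeCutoffCox`."""
    return VolumeCutoffCox(records, knots=knots, reference_value=reference_value).fit()


def find_unit_hr_crossing(
    fit: SplineHazardFit, grid_step: float = 0.5, root_tol: float = 1e-3
) -> CutoffResult:
    """Locate the VC value(s) where the fitted hazard ratio crosses 1.

    The log-HR curve is sampled on a regular grid over the observed VC range;
    every sign change is refined by bracketed root-finding. When the curve
    crosses more than once, the reported cutoff is the up-crossing that best
    separates the cohort into a protective side (HR < 1 below it) and a
    harmful side (HR > 1 above it), scored over the observed VC values —
    the boundary at which shrinking viable volume stops being protective.
    Ties favour the steeper ascent. All roots are returned for inspection.
    """
    lo, hi = fit.vc_range
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    if grid[-1] < hi:
        grid = np.append(grid, hi)
    f = fit.log_hazard_ratio(grid)
    roots: list[float] = []
    for i in range(len(grid) - 1):
        a, b = f[i], f[i + 1]
        if a == 0.0:
            roots.append(float(grid[i]))
        elif a * b < 0:
            roots.append(float(brentq(lambda x: fit.log_hazard_ratio([x])[0],
                                      grid[i], grid[i + 1], xtol=root_tol)))
    if f[-1] == 0.0:
        roots.append(float(grid[-1]))
    # dedupe within tolerance
    deduped: list[float] = []
    for r in sorted(roots):
        if not deduped or r - deduped[-1] > 10 * root_tol:
            deduped.append(r)
    curve = fit.curve()
    if not deduped:
        raise NoCrossingError(
            "the fitted hazard-ratio curve does not cross 1 in the observed VC range",
            curve=curve,
        )

    def slope(x: float) -> float:
        h = max(grid_step / 10, 1e-4)
        xs = np.clip([x - h, x + h], lo, hi)
        ys = fit.log_hazard_ratio(xs)
        return float((ys[1] - ys[0]) / (xs[1] - xs[0]))

    obs = fit.vc_values if fit.vc_values is not None else grid
    f_obs = fit.log_hazard_ratio(obs)

    def separation(r: float) -> float:
        # fraction of observed VC values on the correct side of the boundary
        ok = np.where(obs < r, f_obs <= 0, np.where(obs > r, f_obs >= 0, True))
        return float(np.mean(ok))

    chosen = max(deduped, key=lambda r: (separation(r), slope(r)))
    return CutoffResult(
        cutoff_percent=chosen,
        roots=deduped,
        curve_samples=curve,
        n_used=fit.n_used,
        fit=fit,
    )


def derive_cutoff(records: pd.DataFrame, knots=None, reference_value=None) -> CutoffResult:
    """End-to-end cutoff derivation: spline fit plus HR=1 crossing."""
    return find_unit_hr_crossing(fit_vc_hazard_spline(records, knots, reference_value))
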