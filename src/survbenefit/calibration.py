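"""Calibration-for-benefit: grouped calibration, KM overlays, smooth curves.

Grouped calibration splits participants into quantile groups of predicted
benefit and compares, per group, the mean predicted benefit with the
observed benefit (difference of arm-wise Kaplan-Meier survival at t* for
the SP definition, or of arm-wise RMST at t* for RST).  A linear
regression of observed on predicted over the group points yields the
calibration-for-benefit intercept a0 and slope a1 (ideal: 0 and 1).
Mean bias compares observed and predicted benefit across the whole
sample; MSE/RMSE average the squared group discrepancies.

The smooth (model-based) alternative avoids grouping: the model's two
predicted probabilities at t* are pushed through the complementary
log-log transform, an auxiliary Cox model with a restricted-cubic-spline
basis of the transformed value is fit per arm, and the auxiliary models'
predictions at t* for every participant provide a quasi-observed benefit
to plot against the predicted one.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

from .benefit import SurvivalCurvePair
from .data import TimeGrid, TrialData
from .nonparametric import kaplan_meier, rmst, surv_at

__all__ = [
    "GroupedCalibration",
    "SmoothCalibrationCurve",
    "km_overlay",
    "grouped_calibration",
    "smooth_calibration",
    "rcs_basis",
]


@dataclasses.dataclass(frozen=True)
class GroupedCalibration:
    n_groups: int
    group_size: np.ndarray
    pred_mean: np.ndarray
    pred_min: np.ndarray
    pred_max: np.ndarray
    observed: np.ndarray
    observed_var: np.ndarray
    observed_ci: np.ndarray        # (n_groups, 2)
    group_valid: np.ndarray        # False where an arm was empty / eventless
    a0: float
    a1: float
    a0_ci: tuple[float, float]
    a1_ci: tuple[float, float]
    bias: float
    mse: float
    rmse: float
    definition: str
    horizon: float

    def table(self) -> pd.DataFrame:
        """Tidy per-group table for plotting."""
        return pd.DataFrame(
            {
                "group": np.arange(1, self.n_groups + 1),
                "n": self.group_size,
                "pred_mean": self.pred_mean,
                "pred_min": self.pred_min,
                "pred_max": self.pred_max,
                "observed": self.observed,
                "ci_lower": self.observed_ci[:, 0],
                "ci_upper": self.observed_ci[:, 1],
                "valid": self.group_valid,
            }
        )


@dataclasses.dataclass(frozen=True)
class SmoothCalibrationCurve:
    predicted: np.ndarray
    observed: np.ndarray
    order: np.ndarray      # indices sorting by predicted benefit (plot path)
    knots1: np.ndarray
    knots0: np.ndarray
    horizon: float

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"predicted": self.predicted[self.order], "observed": self.observed[self.order]}
        )


def km_overlay(
    data: TrialData, curves: SurvivalCurvePair, grid: TimeGrid | None = None
) -> dict[int, dict[str, np.ndarray]]:
    """Per-arm observed KM curve versus mean predicted curve.

    For each arm, the Kaplan-Meier estimate of that arm's data is paired
    with the pointwise mean, over the arm's participants, of their
    predicted curve under the arm they actually received.  Returns
    ``{arm: {"times", "km", "pred_times", "pred_mean"}}``.
    """
    if grid is None:
        grid = curves.grid
    out: dict[int, dict[str, np.ndarray]] = {}
    for arm_val in (0, 1):
        mask = data.arm == arm_val
        curve = kaplan_meier(data.subset(mask))
        s = curves.s1 if arm_val == 1 else curves.s0
        out[arm_val] = {
            "times": curve.event_times,
            "km": curve.surv,
            "pred_times": grid.times,
            "pred_mean": s[mask].mean(axis=0),
        }
    return out


def _observed_group_benefit(
    sub: TrialData, definition: str, t_star: float
) -> tuple[float, float, bool]:
    """Observed benefit (KM or RMST difference at t*) and variance within one group."""
    est = {}
    var = {}
    for arm_val in (1, 0):
        mask = sub.arm == arm_val
        if not np.any(mask) or int(np.sum(sub.event[mask])) == 0:
            return np.nan, np.nan, False
        curve = kaplan_meier(sub.subset(mask))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if definition == "SP":
                est[arm_val], var[arm_val] = surv_at(curve, t_star)
            else:
                est[arm_val], var[arm_val] = rmst(curve, t_star)
    return est[1] - est[0], var[1] + var[0], True


def grouped_calibration(
    data: TrialData,
    pred_benefit: np.ndarray,
    t_star: float,
    n_groups: int = 5,
    definition: str = "SP",
    *,
    weighted: bool = False,
    alpha: float = 0.05,
) -> GroupedCalibration:
    """Grouped calibration-for-benefit with intercept, slope, bias and (R)MSE.

    Groups are predicted-benefit quantile bins (sizes equal up to ties).
    ``weighted=True`` switches the calibration regression to
    inverse-variance weights; the default is ordinary least squares.
    """
    definition = definition.upper()
    if definition not in ("SP", "RST"):
        raise ValueError("grouped calibration supports the SP and RST definitions")
    if n_groups != 1 and n_groups < 3:
        raise ValueError(
            "n_groups must be >= 3 (the slope needs at least 3 points); "
            "n_groups=1 gives the bias-only calibration-in-the-large"
        )
    pred = np.asarray(pred_benefit, dtype=float)
    if len(pred) != data.n:
        raise ValueError("predicted benefit must cover every participant")
    if n_groups > 1 and np.ptp(pred) == 0:
        raise ValueError("predicted benefit is constant: calibration slope undefined")

    # quantile bins; ranks break ties so group sizes stay near-equal
    ranks = stats.rankdata(pred, method="ordinal") - 1
    group_of = (ranks * n_groups // data.n).astype(int)

    size = np.empty(n_groups, dtype=int)
    pm = np.empty(n_groups)
    pmin = np.empty(n_groups)
    pmax = np.empty(n_groups)
    obs = np.empty(n_groups)
    ovar = np.empty(n_groups)
    valid = np.ones(n_groups, dtype=bool)
    z = stats.norm.ppf(1 - alpha / 2)
    for gidx in range(n_groups):
        mask = group_of == gidx
        size[gidx] = int(np.sum(mask))
        pm[gidx] = pred[mask].mean()
        pmin[gidx] = pred[mask].min()
        pmax[gidx] = pred[mask].max()
        obs[gidx], ovar[gidx], valid[gidx] = _observed_group_benefit(
            data.subset(mask), definition, t_star
        )
    if not np.all(valid):
        warnings.warn(
            f"{int(np.sum(~valid))} group(s) with an empty or eventless arm excluded "
            "from the calibration regression",
            UserWarning,
            stacklevel=2,
        )
    ci = np.column_stack([obs - z * np.sqrt(ovar), obs + z * np.sqrt(ovar)])

    x = pm[valid]
    y = obs[valid]
    if n_groups == 1:
        # calibration-in-the-large: the single group's observed-minus-predicted
        # is exactly the overall bias; no line is fit.
        if not valid[0]:
            raise ValueError("the whole sample has an empty or eventless arm")
        nan = float("nan")
        return GroupedCalibration(
            n_groups=1, group_size=size, pred_mean=pm, pred_min=pmin, pred_max=pmax,
            observed=obs, observed_var=ovar, observed_ci=ci, group_valid=valid,
            a0=nan, a1=nan, a0_ci=(nan, nan), a1_ci=(nan, nan),
            bias=float(obs[0] - pm[0]),
            mse=float((obs[0] - pm[0]) ** 2),
            rmse=float(abs(obs[0] - pm[0])),
            definition=definition, horizon=t_star,
        )
    if len(x) < 3:
        raise ValueError("fewer than 3 valid groups: calibration line not estimable")
    w = 1.0 / ovar[valid] if weighted else np.ones(len(x))
    W = np.diag(w)
    Xd = np.column_stack([np.ones(len(x)), x])
    xtwx = Xd.T @ W @ Xd
    coef = np.linalg.solve(xtwx, Xd.T @ W @ y)
    resid = y - Xd @ coef
    dof = len(x) - 2
    s2 = float(resid @ (w * resid)) / dof if dof > 0 else np.nan
    cov = s2 * np.linalg.inv(xtwx)
    tq = stats.t.ppf(1 - alpha / 2, dof) if dof > 0 else np.nan
    se = np.sqrt(np.diag(cov))
    a0, a1 = float(coef[0]), float(coef[1])

    # bias: observed minus predicted benefit across the whole sample
    overall_obs, _, overall_ok = _observed_group_benefit(data, definition, t_star)
    bias = float(overall_obs - pred.mean()) if overall_ok else float("nan")
    mse = float(np.mean((y - x) ** 2))
    return GroupedCalibration(
        n_groups=n_groups,
        group_size=size,
        pred_mean=pm,
        pred_min=pmin,
        pred_max=pmax,
        observed=obs,
        observed_var=ovar,
        observed_ci=ci,
        group_valid=valid,
        a0=a0,
        a1=a1,
        a0_ci=(a0 - tq * se[0], a0 + tq * se[0]),
        a1_ci=(a1 - tq * se[1], a1 + tq * se[1]),
        bias=bias,
        mse=mse,
        rmse=float(np.sqrt(mse)),
        definition=definition,
        horizon=t_star,
    )


def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted cubic spline basis (natural spline, linear in the tails).

    With k knots the basis has k - 1 columns: x itself plus k - 2
    truncated-cubic terms, each constrained so the function is linear
    beyond the boundary knots (Harrell's parameterisation).
    """
    knots = np.asarray(knots, dtype=float)
    k = len(knots)
    if k < 3:
        raise ValueError("restricted cubic splines need at least 3 knots")
    x = np.asarray(x, dtype=float)
    t1, tk, tk1 = knots[0], knots[-1], knots[-2]
    scale = (tk - t1) ** 2

    def cub(u):
        return np.clip(u, 0.0, None) ** 3

    cols = [x]
    for j in range(k - 2):
        tj = knots[j]
        term = (
            cub(x - tj)
            - cub(x - tk1) * (tk - tj) / (tk - tk1)
            + cub(x - tk) * (tk1 - tj) / (tk - tk1)
        ) / scale
        cols.append(term)
    return np.column_stack(cols)


_CLL_CLAMP = 1e-10


def _cll(s: np.ndarray) -> np.ndarray:
    """Complementary log-log of the survival probability: log(-log S)."""
    s = np.clip(np.asarray(s, dtype=float), _CLL_CLAMP, 1.0 - _CLL_CLAMP)
    return np.log(-np.log(s))


def smooth_calibration(
    data: TrialData,
    curves: SurvivalCurvePair,
    t_star: float,
    n_knots: int = 3,
) -> SmoothCalibrationCurve:
    """Model-based smooth calibration curve via auxiliary Cox models.

    Per participant: p_z = log(-log S_z(t*)) from the model's predicted
    survival under each arm (clamped away from 0/1).  On each arm's own
    data an auxiliary Cox model is fit with a restricted-cubic-spline
    basis of that arm's p_z (knots at equally spaced quantiles, 10/50/90%
    for three knots); Breslow baseline.  Both auxiliary models are then
    evaluated at t* for *every* participant; the difference of the two
    predictions is the quasi-observed benefit plotted against the
    predicted benefit S1(t*) - S0(t*).
    """
    p1 = _cll(curves.surv_at(1, t_star))
    p0 = _cll(curves.surv_at(0, t_star))
    predicted = curves.surv_at(1, t_star) - curves.surv_at(0, t_star)

    qs = np.linspace(0.1, 0.9, n_knots)
    preds = {}
    knots = {}
    for arm_val, p in ((1, p1), (0, p0)):
        mask = data.arm == arm_val
        kn = np.quantile(p[mask], qs)
        if len(np.unique(kn)) < n_knots:
            raise ValueError(f"degenerate cll values in arm {arm_val}: spline knots coincide")
        basis_fit = rcs_basis(p[mask], kn)
        if int(np.sum(data.event[mask])) <= basis_fit.shape[1]:
            raise ValueError(f"arm {arm_val} has fewer events than spline degrees of freedom")
        df = pd.DataFrame(basis_fit, columns=[f"s{j}" for j in range(basis_fit.shape[1])])
        df["time"] = data.time[mask]
        df["event"] = data.event[mask]
        cph = CoxPHFitter()
        try:
            cph.fit(df, duration_col="time", event_col="event")
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"auxiliary Cox model failed to converge on arm {arm_val}: {exc}") from exc
        basis_all = pd.DataFrame(rcs_basis(p, kn), columns=df.columns[:-2])
        sf = cph.predict_survival_function(basis_all, times=[t_star])
        preds[arm_val] = sf.to_numpy()[0]
        knots[arm_val] = kn
    observed = preds[1] - preds[0]
    return SmoothCalibrationCurve(
        predicted=predicted,
        observed=observed,
        order=np.argsort(predicted, kind="stable"),
        knots1=knots[1],
        knots0=knots[0],
        horizon=t_star,
    )
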