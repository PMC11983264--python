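"""Model adapters and the reference Weibull interaction (S-learner) model.

Any object that can be fit on trial data and produce per-arm survival
curves — or a scalar predicted benefit directly — can be evaluated by the
metrics in this package.  The reference model is an accelerated-failure-
time Weibull regression with linear terms for every covariate, the
treatment indicator, and all treatment-covariate interactions (a single
outcome model spanning both arms, i.e. an S-learner):

    log T = mu + b'x + z (g + d'x) + sigma * eps,   eps ~ standard Gumbel(min)

equivalently S(t | x, z) = exp(-exp((log t - LP) / sigma)) with
LP = mu + b'x + z (g + d'x).  The right-censored log-likelihood is
maximized by quasi-Newton iteration on (mu, b, g, d, log sigma).
"""

from __future__ import annotations

import dataclasses
from typing import Protocol, runtime_checkable

import numpy as np
import pandas as pd
from scipy import optimize
from statsmodels.tools.numdiff import approx_hess1

from .benefit import SurvivalCurvePair, predict_benefit
from .data import TimeGrid, TrialData

__all__ = [
    "BenefitModel",
    "WeibullFit",
    "WeibullSLearner",
    "fit_weibull_slearner",
    "weibull_predict_curves",
    "covariate_design",
]


@runtime_checkable
class BenefitModel(Protocol):
    """Contract for anything the evaluation harness can validate.

    ``predict_benefit`` is mandatory; ``predict_curve_pair`` is an
    optional capability (a model may predict benefit directly without
    per-arm survival curves, in which case curve-based metrics such as
    smooth calibration are unavailable for it).
    """

    def fit(self, train: TrialData) -> "BenefitModel": ...

    def predict_benefit(
        self, covariates: pd.DataFrame, definition: str, horizon: float | None
    ) -> np.ndarray: ...


def covariate_design(cov: pd.DataFrame, reference: pd.DataFrame | None = None) -> tuple[np.ndarray, list[str]]:
    """Numeric design matrix from a covariate frame.

    Numeric columns pass through; categorical/object columns are dummy
    coded with the first level as reference.  ``reference`` (typically
    the training frame) pins the level sets so that train/test designs
    are conformable.
    """
    ref = cov if reference is None else reference
    cols: list[np.ndarray] = []
    names: list[str] = []
    for c in cov.columns:
        ref_col = ref[c]
        if isinstance(ref_col.dtype, pd.CategoricalDtype) or ref_col.dtype == object:
            levels = (
                list(ref_col.cat.categories)
                if isinstance(ref_col.dtype, pd.CategoricalDtype)
                else sorted(ref_col.astype(str).unique())
            )
            vals = cov[c].astype(str)
            for lev in levels[1:]:
                cols.append((vals == str(lev)).to_numpy(float))
                names.append(f"{c}:{lev}")
        else:
            cols.append(cov[c].to_numpy(float))
            names.append(c)
    if not cols:
        return np.empty((len(cov), 0)), []
    return np.column_stack(cols), names


@dataclasses.dataclass(frozen=True)
class WeibullFit:
    """Fitted Weibull interaction model."""

    mu: float
    b: np.ndarray
    g: float
    d: np.ndarray
    log_sigma: float
    vcov: np.ndarray
    loglik: float
    converged: bool
    design_names: list[str]
    reference_covariates: pd.DataFrame  # pins categorical level sets

    @property
    def sigma(self) -> float:
        return float(np.exp(self.log_sigma))

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([[self.mu], self.b, [self.g], self.d, [self.log_sigma]])

    @property
    def param_names(self) -> list[str]:
        return (
            ["(intercept)"]
            + self.design_names
            + ["z"]
            + [f"z:{n}" for n in self.design_names]
            + ["log_sigma"]
        )

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov))

    def linear_predictor(self, cov: pd.DataFrame, arm) -> np.ndarray:
        X, _ = covariate_design(cov, reference=self.reference_covariates)
        arm = np.broadcast_to(np.asarray(arm, dtype=float), (len(cov),))
        return self.mu + X @ self.b + arm * (self.g + X @ self.d)


def _full_design(X: np.ndarray, arm: np.ndarray) -> np.ndarray:
    z = arm.astype(float)[:, None]
    return np.column_stack([np.ones(len(X)), X, z, z * X])


def _check_full_rank(D: np.ndarray, names: list[str]) -> None:
    from scipy.linalg import qr

    _, r, piv = qr(D, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(D.shape) * np.finfo(float).eps
    rank = int(np.sum(diag > tol))
    if rank < D.shape[1]:
        bad = [names[j] for j in piv[rank:]]
        raise np.linalg.LinAlgError(f"design matrix rank deficient; collinear columns: {bad}")


def fit_weibull_slearner(
    train: TrialData,
    *,
    fix_sigma: float | None = None,
    tol: float = 1e-10,
) -> WeibullFit:
    """Maximum-likelihood fit of the Weibull interaction model.

    Parameters
    ----------
    train
        Trial data with at least one observed event.
    fix_sigma
        If given, the scale parameter is held fixed (``fix_sigma=1``
        yields exponential regression, whose rate MLE in the
        intercept-only case is the classic events / total-follow-up).
    tol
        Convergence tolerance passed to the optimizer (gradient norm).
    """
    if train.n_events == 0:
        raise ValueError("cannot fit a survival model to all-censored data (no events)")
    X, names = covariate_design(train.covariates)
    D = _full_design(X, train.arm)
    full_names = ["(intercept)"] + names + ["z"] + [f"z:{n}" for n in names]
    _check_full_rank(D, full_names)

    logt = np.log(train.time)
    c = train.event.astype(float)
    p = D.shape[1]
    free_sigma = fix_sigma is None

    def unpack(theta):
        if free_sigma:
            return theta[:p], theta[p]
        return theta, np.log(fix_sigma)

    def nll(theta):
        coefs, ls = unpack(theta)
        sigma = np.exp(ls)
        w = (logt - D @ coefs) / sigma
        ew = np.exp(np.clip(w, None, 700))
        return -float(np.sum(c * (w - ls - logt) - ew))

    def grad(theta):
        coefs, ls = unpack(theta)
        sigma = np.exp(ls)
        w = (logt - D @ coefs) / sigma
        ew = np.exp(np.clip(w, None, 700))
        g_eta = (ew - c) / sigma          # d loglik / d eta_i
        g_coefs = D.T @ g_eta
        if not free_sigma:
            return -g_coefs
        g_ls = float(np.sum(w * (ew - c) - c))
        return -np.concatenate([g_coefs, [g_ls]])

    theta0 = np.zeros(p + (1 if free_sigma else 0))
    theta0[0] = float(np.log(np.mean(train.time)))
    res = optimize.minimize(nll, theta0, jac=grad, method="L-BFGS-B", options={"gtol": tol, "ftol": 1e-14, "maxiter": 2000})
    if not res.success and np.linalg.norm(grad(res.x)) > 1e-4 * max(1.0, abs(res.fun)):
        raise RuntimeError(f"Weibull fit did not converge: {res.message}")

    coefs, ls = unpack(res.x)
    hess = approx_hess1(res.x, nll)
    try:
        vcov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(hess)
    if not free_sigma:
        # pad vcov with a zero row/col for the fixed log_sigma slot
        v = np.zeros((p + 1, p + 1))
        v[:p, :p] = vcov
        vcov = v
    k = len(names)
    return WeibullFit(
        mu=float(coefs[0]),
        b=np.asarray(coefs[1 : 1 + k]),
        g=float(coefs[1 + k]),
        d=np.asarray(coefs[2 + k : 2 + 2 * k]),
        log_sigma=float(ls),
        vcov=vcov,
        loglik=-float(res.fun),
        converged=bool(res.success),
        design_names=names,
        reference_covariates=train.covariates,
    )


def weibull_predict_curves(
    fit: WeibullFit, cov: pd.DataFrame, arm, grid: TimeGrid
) -> np.ndarray:
    """Survival values S(t | x, arm) on the grid, one row per participant."""
    lp = fit.linear_predictor(cov, arm)
    w = (np.log(grid.times)[None, :] - lp[:, None]) / fit.sigma
    return np.exp(-np.exp(w))


def weibull_curve_pair(fit: WeibullFit, cov: pd.DataFrame, grid: TimeGrid) -> SurvivalCurvePair:
    """Per-participant curve pair under both arms, with the parametric payload."""
    lp1 = fit.linear_predictor(cov, 1)
    lp0 = fit.linear_predictor(cov, 0)
    w = lambda lp: np.exp(-np.exp((np.log(grid.times)[None, :] - lp[:, None]) / fit.sigma))
    return SurvivalCurvePair(
        grid=grid,
        s1=w(lp1),
        s0=w(lp0),
        parametric={"kind": "weibull", "lp1": lp1, "lp0": lp0, "sigma": fit.sigma},
    )


class WeibullSLearner:
    """:class:`BenefitModel` adapter around :func:`fit_weibull_slearner`."""

    def __init__(self, fix_sigma: float | None = None):
        self.fix_sigma = fix_sigma
        self.fit_: WeibullFit | None = None

    def fit(self, train: TrialData) -> "WeibullSLearner":
        self.fit_ = fit_weibull_slearner(train, fix_sigma=self.fix_sigma)
        return self

    def predict_curve_pair(self, cov: pd.DataFrame, grid: TimeGrid) -> SurvivalCurvePair:
        if self.fit_ is None:
            raise RuntimeError("model is not fitted")
        return weibull_curve_pair(self.fit_, cov, grid)

    def predict_curves(self, cov: pd.DataFrame, arm, grid: TimeGrid) -> np.ndarray:
        if self.fit_ is None:
            raise RuntimeError("model is not fitted")
        return weibull_predict_curves(self.fit_, cov, arm, grid)

    def predict_benefit(
        self, cov: pd.DataFrame, definition: str, horizon: float | None, grid: TimeGrid | None = None
    ) -> np.ndarray:
        if grid is None:
            hz = horizon if definition.upper() in ("SP", "RST") else 1.0
            grid = TimeGrid.default(max(2.0 * hz, 1.0))
        return predict_benefit(self.predict_curve_pair(cov, grid), definition, horizon).values
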