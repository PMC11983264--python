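"""Scalar predicted treatment benefit from per-arm survival curves.

Four definitions of participant-level benefit are supported, all signed so
that positive means treatment is better (the event is taken to be harmful):

SP(t*)   difference in survival probability at the horizon, S1(t*) - S0(t*)
RST(t*)  difference in restricted mean survival time, integral of S1 - S0 on [0, t*]
ST       difference in (unrestricted) mean survival time; requires a
         parametric tail, since step curves cannot be extrapolated
PS(p)    difference in the time at which survival reaches the percentile p

A :class:`SurvivalCurvePair` stores both curves on a shared grid; when the
producing model is parametric (exponential / Weibull) the pair also carries
the parametric payload so that RST, ST and PS can be evaluated exactly
instead of by quadrature / inverse interpolation.
"""

from __future__ import annotations

import dataclasses
from math import gamma as gamma_fn

import numpy as np

from .data import TimeGrid

__all__ = [
    "SurvivalCurvePair",
    "BenefitVector",
    "benefit_sp",
    "benefit_rst",
    "benefit_st",
    "benefit_ps",
    "predict_benefit",
]

DEFINITIONS = ("SP", "RST", "ST", "PS")


@dataclasses.dataclass(frozen=True)
class SurvivalCurvePair:
    """Predicted survival under treatment (s1) and control (s0) on a shared grid.

    ``s1``/``s0`` have shape (n_participants, len(grid)), values in [0, 1],
    non-increasing along the grid.  ``parametric``, when present, is a dict
    with keys ``kind`` ("weibull"; exponential is sigma = 1), ``lp1``,
    ``lp0`` (per-participant AFT linear predictors) and ``sigma``.
    """

    grid: TimeGrid
    s1: np.ndarray
    s0: np.ndarray
    parametric: dict | None = None

    def __post_init__(self) -> None:
        s1 = np.atleast_2d(np.asarray(self.s1, dtype=float))
        s0 = np.atleast_2d(np.asarray(self.s0, dtype=float))
        if s1.shape != s0.shape or s1.shape[1] != len(self.grid):
            raise ValueError("curve arrays must be (n, len(grid)) and congruent")
        object.__setattr__(self, "s1", s1)
        object.__setattr__(self, "s0", s0)

    @property
    def n(self) -> int:
        return self.s1.shape[0]

    def surv_at(self, arm: int, t_star: float) -> np.ndarray:
        """Per-participant survival at t*, linearly interpolated (S(0) = 1)."""
        if not 0 < t_star <= self.grid.max_time:
            raise ValueError(f"t*={t_star} outside curve grid (0, {self.grid.max_time}]")
        s = self.s1 if arm == 1 else self.s0
        if self.parametric is not None:
            lp = self.parametric["lp1"] if arm == 1 else self.parametric["lp0"]
            return np.exp(-np.exp((np.log(t_star) - lp) / self.parametric["sigma"]))
        t = np.concatenate([[0.0], self.grid.times])
        sv = np.concatenate([np.ones((self.n, 1)), s], axis=1)
        return np.array([np.interp(t_star, t, row) for row in sv])

    @classmethod
    def from_exponential_rates(
        cls, rate1, rate0, grid: TimeGrid, parametric: bool = True
    ) -> "SurvivalCurvePair":
        r1 = np.atleast_1d(np.asarray(rate1, dtype=float))
        r0 = np.atleast_1d(np.asarray(rate0, dtype=float))
        t = grid.times[None, :]
        pair = cls(
            grid=grid,
            s1=np.exp(-r1[:, None] * t),
            s0=np.exp(-r0[:, None] * t),
            parametric=(
                {"kind": "weibull", "lp1": -np.log(r1), "lp0": -np.log(r0), "sigma": 1.0}
                if parametric
                else None
            ),
        )
        return pair


@dataclasses.dataclass(frozen=True)
class BenefitVector:
    """Per-participant predicted benefit under a named definition and horizon."""

    definition: str
    horizon: float | None
    values: np.ndarray
    undefined_mask: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        m = np.asarray(self.undefined_mask, dtype=bool)
        if v.shape != m.shape:
            raise ValueError("values and mask must be congruent")
        if not np.all(np.isfinite(v[~m])):
            raise ValueError("non-finite benefit outside the undefined mask")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "undefined_mask", m)

    @property
    def n(self) -> int:
        return len(self.values)


def benefit_sp(curves: SurvivalCurvePair, t_star: float) -> np.ndarray:
    """Benefit in survival probability at t*: S1(t*) - S0(t*)."""
    return curves.surv_at(1, t_star) - curves.surv_at(0, t_star)


def benefit_rst(curves: SurvivalCurvePair, t_star: float) -> np.ndarray:
    """Benefit in restricted mean survival time up to t*.

    Exact analytic integral for parametric pairs; composite trapezoid on
    the grid (with the implicit point S(0) = 1) otherwise.
    """
    if not 0 < t_star <= curves.grid.max_time:
        raise ValueError(f"t*={t_star} outside curve grid (0, {curves.grid.max_time}]")
    if curves.parametric is not None:
        p = curves.parametric
        return _weibull_rmst(p["lp1"], p["sigma"], t_star) - _weibull_rmst(p["lp0"], p["sigma"], t_star)
    t = np.concatenate([[0.0], curves.grid.times])
    keep = t <= t_star
    tt = np.concatenate([t[keep], [t_star]]) if t[keep][-1] < t_star else t[keep]

    def integrate(s):
        sv = np.concatenate([np.ones((curves.n, 1)), s], axis=1)
        vals = np.array([np.interp(tt, t, row) for row in sv])
        return np.trapezoid(vals, tt, axis=1)

    return integrate(curves.s1) - integrate(curves.s0)


def benefit_st(curves: SurvivalCurvePair) -> np.ndarray:
    """Benefit in (unrestricted) expected survival time.

    Only defined for parametric pairs: a step/grid curve gives no basis
    for extrapolating the tail beyond the last observation.
    """
    if curves.parametric is None:
        raise ValueError(
            "unrestricted survival benefit requires extrapolation: "
            "only parametric curve pairs support the ST definition"
        )
    p = curves.parametric
    m = gamma_fn(1.0 + p["sigma"])
    return m * (np.exp(np.asarray(p["lp1"])) - np.exp(np.asarray(p["lp0"])))


def benefit_ps(curves: SurvivalCurvePair, p: float) -> BenefitVector:
    """Benefit in percentile survival: t1(p) - t0(p) where S_z(t_z(p)) = p.

    For grid curves the crossing time is found by inverse linear
    interpolation; participants whose curve never reaches p within the
    grid are masked undefined rather than raising.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("percentile p must be in (0, 1)")
    if curves.parametric is not None:
        pr = curves.parametric
        loglog = np.log(-np.log(p))
        t1 = np.exp(np.asarray(pr["lp1"]) + pr["sigma"] * loglog)
        t0 = np.exp(np.asarray(pr["lp0"]) + pr["sigma"] * loglog)
        vals = t1 - t0
        return BenefitVector("PS", p, vals, np.zeros(len(np.atleast_1d(vals)), dtype=bool))
    t = np.concatenate([[0.0], curves.grid.times])
    vals = np.empty(curves.n)
    mask = np.zeros(curves.n, dtype=bool)
    for i in range(curves.n):
        t1 = _crossing_time(t, np.concatenate([[1.0], curves.s1[i]]), p)
        t0 = _crossing_time(t, np.concatenate([[1.0], curves.s0[i]]), p)
        if t1 is None or t0 is None:
            mask[i] = True
            vals[i] = np.nan
        else:
            vals[i] = t1 - t0
    return BenefitVector("PS", p, vals, mask)


def predict_benefit(
    curves: SurvivalCurvePair, definition: str, horizon: float | None
) -> BenefitVector:
    """Dispatch to the requested benefit definition, returning a :class:`BenefitVector`."""
    definition = definition.upper()
    if definition == "SP":
        v = benefit_sp(curves, horizon)
    elif definition == "RST":
        v = benefit_rst(curves, horizon)
    elif definition == "ST":
        v = benefit_st(curves)
        horizon = None
    elif definition == "PS":
        return benefit_ps(curves, horizon)
    else:
        raise ValueError(f"unknown benefit definition {definition!r}; expected one of {DEFINITIONS}")
    v = np.atleast_1d(v)
    return BenefitVector(definition, horizon, v, np.zeros(len(v), dtype=bool))


def _weibull_rmst(lp, sigma: float, t_star: float) -> np.ndarray:
    """Integral of exp(-(t/e^lp)^(1/sigma)) on [0, t*], via the incomplete gamma."""
    from scipy.special import gammainc

    lp = np.asarray(lp, dtype=float)
    lam = np.exp(lp)
    k = 1.0 / sigma
    x = (t_star / lam) ** k
    # int_0^T exp(-(t/lam)^k) dt = lam/k * gamma(1/k) * P(1/k, (T/lam)^k)
    return lam * sigma * gamma_fn(sigma) * gammainc(sigma, x)


def _crossing_time(t: np.ndarray, s: np.ndarray, p: float) -> float | None:
    """First time at which the non-increasing curve s reaches p, or None."""
    below = np.flatnonzero(s <= p)
    if below.size == 0:
        return None
    j = below[0]
    if j == 0 or s[j] == p:
        return float(t[j])
    # linear interpolation between (t[j-1], s[j-1]) and (t[j], s[j])
    s0, s1 = s[j - 1], s[j]
    if s0 == s1:
        return float(t[j])
    return float(t[j - 1] + (s0 - p) / (s0 - s1) * (t[j] - t[j - 1]))
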