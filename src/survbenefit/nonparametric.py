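"""Kaplan-Meier estimation, survival-at-horizon and restricted mean survival time.

Implements the product-limit estimator with Greenwood variance and the
standard large-sample RMST variance directly on step curves.  The step
convention is right-continuous; at tied timestamps events are removed
from the risk set before censorings (the usual KM tie rule).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .data import TrialData

__all__ = ["StepSurvivalCurve", "ExtrapolationWarning", "kaplan_meier", "surv_at", "rmst"]


class ExtrapolationWarning(UserWarning):
    """Evaluation beyond a curve's last observation: flat-tail carry-forward."""


@dataclasses.dataclass(frozen=True)
class StepSurvivalCurve:
    """Kaplan-Meier step curve with Greenwood variance.

    ``event_times`` are the distinct times with at least one event;
    ``surv[j]`` is S(t) just after ``event_times[j]``; ``greenwood_sum``
    accumulates sum d/(n(n-d)) so that Var S(t) = S(t)^2 * greenwood_sum.
    """

    event_times: np.ndarray
    surv: np.ndarray
    greenwood_sum: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    max_follow_up: float

    @property
    def var(self) -> np.ndarray:
        """Greenwood variance of S at each event time."""
        return self.surv**2 * self.greenwood_sum


def kaplan_meier(data: TrialData | None = None, *, time=None, event=None) -> StepSurvivalCurve:
    """Product-limit estimator over a participant subset.

    Accepts either a :class:`TrialData` (possibly an arm subset) or raw
    ``time``/``event`` arrays.
    """
    if data is not None:
        time, event = data.time, data.event
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("empty subset: Kaplan-Meier undefined")
    n = time.size
    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    e_sorted = event[order]

    # distinct times with >=1 event; risk set at t counts everyone with T >= t
    uniq, inv = np.unique(t_sorted, return_inverse=True)
    d = np.bincount(inv, weights=e_sorted)            # events per distinct time
    removed = np.bincount(inv)                        # all leaving at this time
    at_risk = n - np.concatenate([[0], np.cumsum(removed)[:-1]])

    has_event = d > 0
    et = uniq[has_event]
    dj = d[has_event]
    nj = at_risk[has_event].astype(float)

    frac = 1.0 - dj / nj
    surv = np.cumprod(frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        incr = np.where(nj > dj, dj / (nj * (nj - dj)), np.inf)
    gw = np.cumsum(incr)
    # once S hits 0 its variance is conventionally 0
    gw = np.where(surv > 0, gw, 0.0)
    return StepSurvivalCurve(
        event_times=et,
        surv=surv,
        greenwood_sum=gw,
        n_at_risk=nj,
        n_events=dj,
        max_follow_up=float(t_sorted[-1]),
    )


def _step_index(curve: StepSurvivalCurve, t: float) -> int:
    """Number of event times <= t (right-continuous evaluation)."""
    return int(np.searchsorted(curve.event_times, t, side="right"))


def surv_at(curve: StepSurvivalCurve, t_star: float) -> tuple[float, float]:
    """Survival estimate and Greenwood variance at ``t_star``.

    Right-continuous: at an event time the value *after* the drop is
    returned.  Beyond the last follow-up time the last value is carried
    flat and an :class:`ExtrapolationWarning` is emitted.
    """
    if t_star <= 0:
        raise ValueError("t_star must be positive")
    if t_star > curve.max_follow_up:
        warnings.warn(
            f"t*={t_star} beyond last follow-up {curve.max_follow_up}: carrying the curve flat",
            ExtrapolationWarning,
            stacklevel=2,
        )
    k = _step_index(curve, t_star)
    if k == 0:
        return 1.0, 0.0
    s = float(curve.surv[k - 1])
    return s, float(s * s * curve.greenwood_sum[k - 1])


def rmst(curve: StepSurvivalCurve, t_star: float) -> tuple[float, float]:
    """Restricted mean survival time: area under the step curve on [0, t*].

    Variance by the standard large-sample formula
    ``sum_j A_j^2 * d_j / (n_j (n_j - d_j))`` where ``A_j`` is the area
    under the curve from event time j to t*.
    """
    if t_star <= 0:
        raise ValueError("t_star must be positive")
    if t_star > curve.max_follow_up:
        warnings.warn(
            f"t*={t_star} beyond last follow-up {curve.max_follow_up}: carrying the curve flat",
            ExtrapolationWarning,
            stacklevel=2,
        )
    k = _step_index(curve, t_star)
    if k == 0:
        return float(t_star), 0.0
    et = curve.event_times[:k]
    s = curve.surv[:k]
    # rectangle widths: [0,t1), [t1,t2), ..., [tk, t*]
    edges = np.concatenate([[0.0], et, [t_star]])
    widths = np.diff(edges)
    heights = np.concatenate([[1.0], s])
    area = float(np.sum(widths * heights))

    # remaining area from each event time to t*
    cum_from_right = np.concatenate([[0.0], np.cumsum((widths[1:] * heights[1:])[::-1])])[::-1]
    a_j = cum_from_right[:-1] if cum_from_right.size > 1 else np.array([])
    nj = curve.n_at_risk[:k]
    dj = curve.n_events[:k]
    with np.errstate(divide="ignore", invalid="ignore"):
        incr = np.where(nj > dj, dj / (nj * (nj - dj)), 0.0)
    var = float(np.sum(a_j**2 * incr)) if a_j.size else 0.0
    return area, var
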