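"""Decision accuracy: population benefit of treating according to a model.

A benefit threshold b_th (default 0) turns predicted benefit into a
treatment recommendation; crossing it with the arm actually received
partitions the trial into four groups:

    g1  recommended treatment, received treatment   (optimal)
    g2  recommended treatment, received control     (suboptimal)
    g3  recommended control,   received treatment   (suboptimal)
    g4  recommended control,   received control     (optimal)

Because out-of-sample predicted benefit is a baseline variable,
randomization makes the contrast of g1 u g4 (treated per the model)
against g2 u g3 (treated opposite to the model) unconfounded.  With
K(A) the Kaplan-Meier survival (or RMST) of participant set A at t*:

    PB    = K(g1 u g4) - K(g2 u g3)   model vs its opposite
    PBvC  = K(g1 u g4) - K(g2 u g4)   model vs treating no-one
    PBvT  = K(g1 u g4) - K(g1 u g3)   model vs treating everyone

and K(g3) - K(g4) is the observed treatment effect in the subgroup the
model recommends *against* treating — negative when the model correctly
finds participants harmed by treatment.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .data import TrialData
from .nonparametric import kaplan_meier, rmst, surv_at

__all__ = ["DecisionGroups", "PBResult", "assign_groups", "population_benefit"]


@dataclasses.dataclass(frozen=True)
class DecisionGroups:
    b_th: float
    recommend: np.ndarray  # boolean: predicted benefit > b_th
    g1: np.ndarray
    g2: np.ndarray
    g3: np.ndarray
    g4: np.ndarray

    @property
    def recommend_rate(self) -> float:
        return float(np.mean(self.recommend))


@dataclasses.dataclass(frozen=True)
class PBResult:
    pb: float
    pb_vc: float
    pb_vt: float
    subgroup_neg_effect: float
    pb_ci: tuple[float, float]
    pb_vc_ci: tuple[float, float]
    pb_vt_ci: tuple[float, float]
    subgroup_neg_effect_ci: tuple[float, float]
    definition: str
    horizon: float
    n_groups: dict[str, int]
    ci_method: str
    undefined: tuple[str, ...] = ()


def assign_groups(
    data: TrialData, pred_benefit: np.ndarray, b_th: float = 0.0
) -> DecisionGroups:
    """Partition participants by recommendation (B > b_th, ties to control) and arm."""
    pred = np.asarray(pred_benefit, dtype=float)
    if len(pred) != data.n:
        raise ValueError("predicted benefit must cover every participant")
    bad = np.flatnonzero(~np.isfinite(pred))
    if bad.size:
        raise ValueError(f"undefined predicted benefit for ids: {list(data.ids[bad[:10]])}")
    rec = pred > b_th
    z = data.arm == 1
    return DecisionGroups(
        b_th=b_th,
        recommend=rec,
        g1=np.flatnonzero(rec & z),
        g2=np.flatnonzero(rec & ~z),
        g3=np.flatnonzero(~rec & z),
        g4=np.flatnonzero(~rec & ~z),
    )


def _k(data: TrialData, idx: np.ndarray, definition: str, t_star: float) -> float:
    if idx.size == 0:
        return np.nan
    curve = kaplan_meier(time=data.time[idx], event=data.event[idx])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if definition == "SP":
            return surv_at(curve, t_star)[0]
        return rmst(curve, t_star)[0]


def _contrasts(data: TrialData, groups: DecisionGroups, definition: str, t_star: float):
    g1, g2, g3, g4 = groups.g1, groups.g2, groups.g3, groups.g4
    follow = np.concatenate([g1, g4])   # treated according to the model
    oppose = np.concatenate([g2, g3])
    k_follow = _k(data, follow, definition, t_star)
    pb = k_follow - _k(data, oppose, definition, t_star)
    pb_vc = k_follow - _k(data, np.concatenate([g2, g4]), definition, t_star)
    pb_vt = k_follow - _k(data, np.concatenate([g1, g3]), definition, t_star)
    sub = _k(data, g3, definition, t_star) - _k(data, g4, definition, t_star)
    return pb, pb_vc, pb_vt, sub


def population_benefit(
    groups: DecisionGroups,
    data: TrialData,
    definition: str = "SP",
    t_star: float = 2.0,
    ci: str = "bootstrap",
    n_boot: int = 1000,
    seed: int | None = None,
    *,
    alpha: float = 0.05,
    pred_benefit: np.ndarray | None = None,
) -> PBResult:
    """Population-benefit estimands with bootstrap confidence intervals.

    ``ci="bootstrap"`` resamples participants with replacement (the group
    partition is re-derived per resample from the fixed recommendations,
    which handles the overlap of g1 between the PBvC/PBvT unions);
    ``ci="none"`` skips uncertainty.
    """
    definition = definition.upper()
    if definition not in ("SP", "RST"):
        raise ValueError("population benefit supports the SP and RST definitions")
    pb, pb_vc, pb_vt, sub = _contrasts(data, groups, definition, t_star)
    undefined = tuple(
        name
        for name, val in (("pb", pb), ("pb_vc", pb_vc), ("pb_vt", pb_vt), ("subgroup_neg_effect", sub))
        if not np.isfinite(val)
    )
    nan_ci = (float("nan"), float("nan"))
    if ci == "none":
        return PBResult(
            pb=pb, pb_vc=pb_vc, pb_vt=pb_vt, subgroup_neg_effect=sub,
            pb_ci=nan_ci, pb_vc_ci=nan_ci, pb_vt_ci=nan_ci, subgroup_neg_effect_ci=nan_ci,
            definition=definition, horizon=t_star,
            n_groups={"g1": groups.g1.size, "g2": groups.g2.size, "g3": groups.g3.size, "g4": groups.g4.size},
            ci_method="none", undefined=undefined,
        )
    if ci != "bootstrap":
        raise ValueError(f"unknown ci method {ci!r}")
    rng = np.random.default_rng(seed)
    rec = groups.recommend
    boot = np.full((n_boot, 4), np.nan)
    for b in range(n_boot):
        idx = rng.integers(0, data.n, data.n)
        bdata = data.subset(idx)
        bgroups = DecisionGroups(
            b_th=groups.b_th,
            recommend=rec[idx],
            g1=np.flatnonzero(rec[idx] & (bdata.arm == 1)),
            g2=np.flatnonzero(rec[idx] & (bdata.arm == 0)),
            g3=np.flatnonzero(~rec[idx] & (bdata.arm == 1)),
            g4=np.flatnonzero(~rec[idx] & (bdata.arm == 0)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            boot[b] = _contrasts(bdata, bgroups, definition, t_star)
    qs = np.nanpercentile(boot, [100 * alpha / 2, 100 * (1 - alpha / 2)], axis=0)
    return PBResult(
        pb=pb, pb_vc=pb_vc, pb_vt=pb_vt, subgroup_neg_effect=sub,
        pb_ci=(qs[0, 0], qs[1, 0]),
        pb_vc_ci=(qs[0, 1], qs[1, 1]),
        pb_vt_ci=(qs[0, 2], qs[1, 2]),
        subgroup_neg_effect_ci=(qs[0, 3], qs[1, 3]),
        definition=definition, horizon=t_star,
        n_groups={"g1": groups.g1.size, "g2": groups.g2.size, "g3": groups.g3.size, "g4": groups.g4.size},
        ci_method="bootstrap", undefined=undefined,
    )
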