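"""C-for-benefit: discrimination of models predicting treatment benefit.

Participant-level benefit is never observed, so treated-control pairs of
"similar" participants stand in for it: the pair's observed benefit is +1
if the shorter follow-up time in the pair was an event in the control
member, -1 if it was an event in the treated member, and 0 if the shorter
follow-up was censored.  C-for-benefit is then the probability that, of
two matched pairs with unequal observed benefit, the pair with the
greater observed benefit also has the higher predicted benefit — 0.5 is
uninformative, 1 perfect.

Pairs are matched either on predicted benefit (rank matching) or on
baseline covariates (greedy Mahalanobis or propensity-score nearest
neighbor).  With unequal arm sizes the excess members of the larger arm
are excluded at random, so the whole matching is replicated (default 100
times) and results averaged.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import norm

from .data import TrialData
from .models import covariate_design

__all__ = [
    "MatchedPairSet",
    "CForBenefitResult",
    "observed_pair_benefit",
    "match_by_benefit",
    "match_by_covariates",
    "concordance_for_benefit",
    "c_for_benefit",
]


@dataclasses.dataclass(frozen=True)
class MatchedPairSet:
    """1:1 treated-control pairs with observed and predicted pair benefit."""

    treated_idx: np.ndarray
    control_idx: np.ndarray
    observed_benefit: np.ndarray   # per pair, in {-1, 0, +1}
    pair_pred_benefit: np.ndarray
    matching_mode: str
    replicate_seed: int | None
    treated_ids: np.ndarray | None = None
    control_ids: np.ndarray | None = None

    @property
    def n_pairs(self) -> int:
        return len(self.treated_idx)


@dataclasses.dataclass(frozen=True)
class CForBenefitResult:
    estimate: float
    ci_lower: float
    ci_upper: float
    n_replicates: int
    per_replicate: np.ndarray
    defined: bool = True


def observed_pair_benefit(treated: tuple[float, int], control: tuple[float, int]) -> int:
    """Observed benefit of one treated-control pair.

    The member with the shorter follow-up decides: an event in the
    control member means the treated member outlived them (+1), an event
    in the treated member means the opposite (-1), and a censored shorter
    follow-up is uninformative (0).  Equal follow-up times with events in
    both members are also scored 0 (neither is shorter).
    """
    t_t, c_t = treated
    t_c, c_c = control
    if t_c < t_t:
        return +1 if c_c == 1 else 0
    if t_t < t_c:
        return -1 if c_t == 1 else 0
    return 0


def _observed_benefit_vec(tt, ct, tc, cc) -> np.ndarray:
    out = np.zeros(len(tt), dtype=int)
    out[(tc < tt) & (cc == 1)] = 1
    out[(tt < tc) & (ct == 1)] = -1
    return out


def _balanced_arms(data: TrialData, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Indices of both arms after randomly excluding the larger arm's excess."""
    treated = np.flatnonzero(data.arm == 1)
    control = np.flatnonzero(data.arm == 0)
    if len(treated) == 0 or len(control) == 0:
        raise ValueError("both arms must be non-empty for matching")
    m = min(len(treated), len(control))
    if len(treated) > m:
        treated = rng.choice(treated, size=m, replace=False)
    if len(control) > m:
        control = rng.choice(control, size=m, replace=False)
    return treated, control


def match_by_benefit(
    data: TrialData, pred_benefit: np.ndarray, seed: int | None = None
) -> MatchedPairSet:
    """Rank matching: sort each (balanced) arm by predicted benefit and pair equal ranks."""
    rng = np.random.default_rng(seed)
    pred_benefit = np.asarray(pred_benefit, dtype=float)
    treated, control = _balanced_arms(data, rng)
    treated = treated[np.argsort(pred_benefit[treated], kind="stable")]
    control = control[np.argsort(pred_benefit[control], kind="stable")]
    obs = _observed_benefit_vec(
        data.time[treated], data.event[treated], data.time[control], data.event[control]
    )
    return MatchedPairSet(
        treated_idx=treated,
        control_idx=control,
        observed_benefit=obs,
        pair_pred_benefit=0.5 * (pred_benefit[treated] + pred_benefit[control]),
        matching_mode="by_benefit",
        replicate_seed=seed,
        treated_ids=data.ids[treated],
        control_ids=data.ids[control],
    )


def match_by_covariates(
    data: TrialData,
    pred_benefit: np.ndarray,
    seed: int | None = None,
    *,
    method: str = "mahalanobis",
) -> MatchedPairSet:
    """Greedy 1:1 nearest-neighbor matching without replacement on covariates.

    ``method="mahalanobis"`` (default) uses Mahalanobis distance on
    standardized dummy-coded covariates; ``method="propensity"`` matches
    on an estimated logistic propensity score.  Treated participants are
    processed in seeded random order; with unequal arms the excess of the
    larger arm stays unmatched (exclusion re-drawn per replicate).
    """
    rng = np.random.default_rng(seed)
    pred_benefit = np.asarray(pred_benefit, dtype=float)
    X, _ = covariate_design(data.covariates)
    if X.shape[1] == 0:
        raise ValueError("covariate matching needs at least one covariate")
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - X.mean(axis=0)) / sd

    treated, control = _balanced_arms(data, rng)
    if method == "propensity":
        from sklearn.linear_model import LogisticRegression

        lr = LogisticRegression(C=np.inf, max_iter=1000)
        lr.fit(Xs, data.arm)
        score = lr.decision_function(Xs)[:, None]
        dist = np.abs(score[treated] - score[control].T)
    elif method == "mahalanobis":
        cov = np.cov(Xs, rowvar=False)
        cov = np.atleast_2d(cov)
        try:
            vi = np.linalg.inv(cov)
            dist = cdist(Xs[treated], Xs[control], metric="mahalanobis", VI=vi)
        except np.linalg.LinAlgError:
            import warnings

            warnings.warn(
                "singular covariate covariance; falling back to Euclidean distance",
                UserWarning,
                stacklevel=2,
            )
            dist = cdist(Xs[treated], Xs[control], metric="euclidean")
    else:
        raise ValueError(f"unknown matching method {method!r}")

    order = rng.permutation(len(treated))
    taken = np.zeros(len(control), dtype=bool)
    pair_t = np.empty(len(treated), dtype=int)
    pair_c = np.empty(len(treated), dtype=int)
    for k, i in enumerate(order):
        row = np.where(taken, np.inf, dist[i])
        j = int(np.argmin(row))
        taken[j] = True
        pair_t[k] = treated[i]
        pair_c[k] = control[j]
    obs = _observed_benefit_vec(
        data.time[pair_t], data.event[pair_t], data.time[pair_c], data.event[pair_c]
    )
    return MatchedPairSet(
        treated_idx=pair_t,
        control_idx=pair_c,
        observed_benefit=obs,
        pair_pred_benefit=0.5 * (pred_benefit[pair_t] + pred_benefit[pair_c]),
        matching_mode="by_covariates",
        replicate_seed=seed,
        treated_ids=data.ids[pair_t],
        control_ids=data.ids[pair_c],
    )


def concordance_for_benefit(pairs: MatchedPairSet) -> tuple[float, float]:
    """Concordance and a U-statistic variance estimate over one pair set.

    Over all combinations of two pairs with unequal observed benefit,
    counts those where the pair with greater observed benefit has the
    strictly higher predicted benefit; predicted-benefit ties score 0.5.
    Runs in O(P log P) by sorting within the three observed-benefit
    classes.  Returns (nan, nan) when no comparable combination exists.
    """
    obs = pairs.observed_benefit
    pred = pairs.pair_pred_benefit
    classes = [pred[obs == v] for v in (-1, 0, 1)]
    sorted_classes = [np.sort(c) for c in classes]
    counts = [len(c) for c in classes]

    total = 0.0
    denom = 0
    # per-pair concordance components for the variance estimate
    comp_sum = [np.zeros(n) for n in counts]
    comp_w = [0] * 3
    for lo in range(3):
        for hi in range(lo + 1, 3):
            n_lo, n_hi = counts[lo], counts[hi]
            if n_lo == 0 or n_hi == 0:
                continue
            lo_sorted = sorted_classes[lo]
            # for each member of the higher class: #lower-class preds strictly below, ties
            below = np.searchsorted(lo_sorted, classes[hi], side="left")
            ties_hi = np.searchsorted(lo_sorted, classes[hi], side="right") - below
            score_hi = below + 0.5 * ties_hi
            total += float(np.sum(score_hi))
            denom += n_lo * n_hi
            comp_sum[hi] += score_hi
            comp_w[hi] += n_lo
            hi_sorted = sorted_classes[hi]
            above = n_hi - np.searchsorted(hi_sorted, classes[lo], side="right")
            ties_lo = np.searchsorted(hi_sorted, classes[lo], side="right") - np.searchsorted(
                hi_sorted, classes[lo], side="left"
            )
            comp_sum[lo] += above + 0.5 * ties_lo
            comp_w[lo] += n_hi
    if denom == 0:
        return float("nan"), float("nan")
    c = total / denom
    var = 0.0
    for k in range(3):
        if comp_w[k] == 0 or counts[k] == 0:
            continue
        ck = comp_sum[k] / comp_w[k]                     # per-item mean score
        var += float(np.sum((comp_w[k] * (ck - c)) ** 2)) / denom**2
    return c, var


def c_for_benefit(
    data: TrialData,
    pred_benefit: np.ndarray,
    mode: str = "by_benefit",
    n_replicates: int = 100,
    seed: int | None = None,
    *,
    covariate_method: str = "mahalanobis",
    alpha: float = 0.05,
) -> CForBenefitResult:
    """C-for-benefit with repeated matching.

    Each replicate re-draws the larger-arm exclusions and re-pairs; the
    estimate is the mean concordance over replicates.  The CI is a normal
    approximation from the per-replicate U-statistic variance with
    endpoints averaged over replicates — it deliberately ignores
    uncertainty in the matching procedure itself.
    """
    rng = np.random.default_rng(seed)
    pred_benefit = np.asarray(pred_benefit, dtype=float)
    n_t = int(np.sum(data.arm == 1))
    n_c = data.n - n_t
    if n_t == n_c and mode == "by_benefit":
        n_replicates = 1  # matching is deterministic: nothing to replicate
    cs = np.empty(n_replicates)
    lo = np.empty(n_replicates)
    hi = np.empty(n_replicates)
    z = norm.ppf(1 - alpha / 2)
    for r in range(n_replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        if mode == "by_benefit":
            pairs = match_by_benefit(data, pred_benefit, seed=rep_seed)
        elif mode == "by_covariates":
            pairs = match_by_covariates(data, pred_benefit, seed=rep_seed, method=covariate_method)
        else:
            raise ValueError(f"unknown matching mode {mode!r}")
        c, var = concordance_for_benefit(pairs)
        cs[r] = c
        se = np.sqrt(var) if np.isfinite(var) else np.nan
        lo[r] = c - z * se
        hi[r] = c + z * se
    if np.all(np.isnan(cs)):
        return CForBenefitResult(
            estimate=float("nan"),
            ci_lower=float("nan"),
            ci_upper=float("nan"),
            n_replicates=n_replicates,
            per_replicate=cs,
            defined=False,
        )
    return CForBenefitResult(
        estimate=float(np.nanmean(cs)),
        ci_lower=float(np.nanmean(lo)),
        ci_upper=float(np.nanmean(hi)),
        n_replicates=n_replicates,
        per_replicate=cs,
    )
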