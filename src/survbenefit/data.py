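"""Participant-level trial data model and delimited-text I/O.

The universal input for every metric in this package is one row per trial
participant: a strictly positive follow-up time, an event indicator
(1 = event observed, 0 = censored), a randomized arm indicator
(1 = treatment, 0 = control), and a named vector of baseline covariates.
Missing baseline data are rejected rather than imputed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrialData",
    "TimeGrid",
    "SchemaError",
    "ValidationError",
    "read_trial_csv",
    "write_metrics_report",
]


class SchemaError(ValueError):
    """A required column is absent from the input file."""


class ValidationError(ValueError):
    """A cell violates the trial-data invariants (reported with its row)."""


@dataclasses.dataclass(frozen=True)
class TrialData:
    """Validated right-censored RCT data.

    Parameters
    ----------
    ids
        Opaque participant identifiers (preserved so matched pairs and
        group memberships remain auditable).
    time
        Follow-up time, strictly positive, in data units (e.g. years).
    event
        1 if the event was observed at ``time``, 0 if censored.
    arm
        1 for treatment, 0 for control.
    covariates
        Baseline covariate frame, one row per participant, numeric or
        categorical columns, no missing values.
    """

    ids: np.ndarray
    time: np.ndarray
    event: np.ndarray
    arm: np.ndarray
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        n = len(self.ids)
        for name in ("time", "event", "arm"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"{name} has length {len(getattr(self, name))}, expected {n}")
        if len(self.covariates) != n:
            raise ValidationError("covariate frame length mismatch")
        bad = np.flatnonzero(~(self.time > 0))
        if bad.size:
            raise ValidationError(f"non-positive follow-up time at row {bad[0]}")
        for name, arr in (("event", self.event), ("arm", self.arm)):
            bad = np.flatnonzero(~np.isin(arr, (0, 1)))
            if bad.size:
                raise ValidationError(f"{name} outside {{0,1}} at row {bad[0]}")
        if self.covariates.isna().any().any():
            col = self.covariates.columns[self.covariates.isna().any()][0]
            row = int(self.covariates[col].isna().idxmax())
            raise ValidationError(f"missing value in covariate {col!r} at row {row}")
        for arm_val in (0, 1):
            if not np.any(self.arm == arm_val):
                raise ValidationError(f"arm {arm_val} is empty")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_treated(self) -> int:
        return int(np.sum(self.arm == 1))

    @property
    def n_control(self) -> int:
        return int(np.sum(self.arm == 0))

    @property
    def n_events(self) -> int:
        return int(np.sum(self.event == 1))

    @property
    def covariate_names(self) -> list[str]:
        return list(self.covariates.columns)

    def subset(self, mask: np.ndarray) -> "TrialData":
        """Row subset; ``mask`` is boolean or an index array.

        The subset is *not* revalidated for both-arms-nonempty (KM on a
        single arm is a legitimate use), so this constructs directly.
        """
        idx = np.arange(self.n)[mask]
        sub = TrialData.__new__(TrialData)
        object.__setattr__(sub, "ids", self.ids[idx])
        object.__setattr__(sub, "time", self.time[idx])
        object.__setattr__(sub, "event", self.event[idx])
        object.__setattr__(sub, "arm", self.arm[idx])
        object.__setattr__(sub, "covariates", self.covariates.iloc[idx].reset_index(drop=True))
        return sub

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"id": self.ids, "time": self.time, "event": self.event, "arm": self.arm})
        return pd.concat([df, self.covariates.reset_index(drop=True)], axis=1)

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        *,
        time_col: str = "time",
        event_col: str = "event",
        arm_col: str = "arm",
        id_col: str | None = "id",
        covariate_cols: Sequence[str] | None = None,
    ) -> "TrialData":
        for col in (time_col, event_col, arm_col):
            if col not in df.columns:
                raise SchemaError(f"required column {col!r} not found")
        if covariate_cols is None:
            drop = {time_col, event_col, arm_col}
            if id_col is not None and id_col in df.columns:
                drop.add(id_col)
            covariate_cols = [c for c in df.columns if c not in drop]
        else:
            missing = [c for c in covariate_cols if c not in df.columns]
            if missing:
                raise SchemaError(f"covariate column {missing[0]!r} not found")
        for col in (time_col, event_col, arm_col, *covariate_cols):
            if df[col].isna().any():
                row = int(df[col].isna().idxmax())
                raise ValidationError(f"missing value in column {col!r} at row {row}")
        if id_col is not None and id_col in df.columns:
            ids = df[id_col].astype(str).to_numpy()
        else:
            ids = np.array([str(i) for i in range(len(df))])
        cov = df[list(covariate_cols)].reset_index(drop=True).copy()
        for c in cov.columns:
            if cov[c].dtype == object:
                cov[c] = cov[c].astype("category")
        return cls(
            ids=ids,
            time=df[time_col].to_numpy(dtype=float),
            event=df[event_col].to_numpy(dtype=int),
            arm=df[arm_col].to_numpy(dtype=int),
            covariates=cov,
        )


@dataclasses.dataclass(frozen=True)
class TimeGrid:
    """Shared evaluation grid for storing per-participant survival curves."""

    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or t.size == 0:
            raise ValueError("grid must be a non-empty 1-d array")
        if t[0] <= 0 or np.any(np.diff(t) <= 0):
            raise ValueError("grid times must be strictly increasing and positive")
        object.__setattr__(self, "times", t)

    @classmethod
    def default(cls, max_time: float, n_points: int = 200) -> "TimeGrid":
        """Evenly spaced grid on (0, max_time], 200 points by default."""
        return cls(np.linspace(max_time / n_points, max_time, n_points))

    @property
    def max_time(self) -> float:
        return float(self.times[-1])

    def __len__(self) -> int:
        return len(self.times)


def read_trial_csv(
    path: str | Path,
    *,
    time_col: str = "time",
    event_col: str = "event",
    arm_col: str = "arm",
    id_col: str | None = "id",
    covariate_cols: Sequence[str] | None = None,
) -> TrialData:
    """Read participant-level trial data from a delimited text file.

    Columns not mapped are ignored when ``covariate_cols`` is given;
    otherwise every unmapped column is taken as a covariate.  Row order is
    preserved.  Missing cells, non-positive times, and event/arm values
    outside {0, 1} raise :class:`ValidationError` naming the row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    return TrialData.from_frame(
        df,
        time_col=time_col,
        event_col=event_col,
        arm_col=arm_col,
        id_col=id_col,
        covariate_cols=covariate_cols,
    )


def write_metrics_report(
    results: Sequence[Mapping],
    path: str | Path,
    *,
    tables: Mapping[str, pd.DataFrame] | None = None,
) -> None:
    """Write a machine-readable metrics report.

    ``results`` is a sequence of flat records (name, estimate, ci_lower,
    ci_upper, horizon, definition, ...); it is serialized as JSON to
    ``path``.  Tidy plot tables (grouped-calibration points, smooth-curve
    point sets, overlay curves) are written as CSV next to the report,
    one file per table, named ``<stem>_<table>.csv``.
    """
    path = Path(path)
    records = [dict(r) for r in results]
    with open(path, "w") as fh:
        json.dump({"metrics": records}, fh, indent=2, default=_json_default)
        fh.write("\n")
    if tables:
        for name, table in tables.items():
            table.to_csv(path.with_name(f"{path.stem}_{name}.csv"), index=False)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
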