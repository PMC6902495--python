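"""Long-format trial dataset: one row per participant, one column per
endpoint, with entry times and per-endpoint observation lags."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import LookCounts, ModelError

DEFAULT_LAGS = (3.0, 6.0, 12.0)


@dataclass(frozen=True)
class TrialDataset:
    """Participant-level outcome records.

    ``values[i, k]`` is participant ``i``'s measurement of endpoint ``k``
    (NaN if missing).  Endpoint ``k`` becomes observable ``lags[k]`` months
    after the participant's entry time; restricting the dataset to a calendar
    time masks any value whose observation time lies in the future.
    """

    values: np.ndarray
    arms: np.ndarray
    entries: np.ndarray
    lags: tuple = DEFAULT_LAGS
    pids: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        arms = np.asarray(self.arms, dtype=int)
        entries = np.asarray(self.entries, dtype=float)
        lags = tuple(float(x) for x in self.lags)
        if v.shape[0] != arms.size or v.shape[0] != entries.size:
            raise ModelError("values, arms and entries must agree on the number of participants")
        if v.shape[1] != len(lags):
            raise ModelError("number of outcome columns must match number of lags")
        if not np.all(np.isin(arms, (0, 1))):
            raise ModelError("arm must be 0 (control) or 1 (active)")
        if np.any(np.isinf(v)):
            raise ModelError("outcome values must be finite or missing")
        pids = self.pids
        if pids is None:
            pids = np.arange(v.shape[0])
        else:
            pids = np.asarray(pids)
            if pids.size != v.shape[0]:
                raise ModelError("pids must have one entry per participant")
            if pd.Index(pids).has_duplicates:
                raise ModelError("participant ids must be unique")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "arms", arms)
        object.__setattr__(self, "entries", entries)
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "pids", pids)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def K(self) -> int:
        return self.values.shape[1]

    def available_times(self) -> np.ndarray:
        """Calendar time at which each value becomes observable (inf where
        the value is missing outright)."""
        t = self.entries[:, None] + np.asarray(self.lags)[None, :]
        return np.where(np.isnan(self.values), np.inf, t)

    def at(self, time: float) -> "TrialDataset":
        """Snapshot of the dataset as observable at a calendar time."""
        mask = self.available_times() <= time
        vals = np.where(mask, self.values, np.nan)
        return TrialDataset(vals, self.arms, self.entries, self.lags, self.pids)

    def counts(self) -> LookCounts:
        """Per-arm observed counts for each endpoint.

        If missingness is non-monotone the raw per-endpoint counts may not be
        nested; they are repaired to the tightest nested envelope (running
        maximum from the final endpoint backwards) so that the variance
        formula remains evaluable.
        """
        obs = ~np.isnan(self.values)
        raw = np.column_stack([obs[self.arms == 0].sum(axis=0), obs[self.arms == 1].sum(axis=0)])
        nested = np.maximum.accumulate(raw[::-1], axis=0)[::-1]
        return LookCounts(nested)

    def observed(self, k: int, arm: int) -> np.ndarray:
        """Values of endpoint ``k`` observed in ``arm``."""
        sel = (self.arms == arm) & ~np.isnan(self.values[:, k])
        return self.values[sel, k]

    def to_frame(self) -> pd.DataFrame:
        cols = {"participant_id": self.pids, "arm": self.arms, "entry_month": self.entries}
        for k, lag in enumerate(self.lags):
            cols[f"outcome_{int(lag)}m"] = self.values[:, k]
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, lags: tuple = DEFAULT_LAGS) -> "TrialDataset":
        outcome_cols = [f"outcome_{int(lag)}m" for lag in lags]
        missing = [c for c in ("participant_id", "arm", "entry_month", *outcome_cols) if c not in df.columns]
        if missing:
            raise ModelError(f"dataset is missing required columns: {missing}")
        values = df[outcome_cols].to_numpy(dtype=float)
        return cls(
            values=values,
            arms=df["arm"].to_numpy(),
            entries=df["entry_month"].to_numpy(dtype=float),
            lags=lags,
            pids=df["participant_id"].to_numpy(),
        )
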