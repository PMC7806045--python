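"""In-memory containers for recordings, event schedules and epochs.

The paradigm: a robot highlights each of ``n_objects`` candidate objects
with a laser pointer in 3 s sequences of brief (100 ms) stimuli; the user
attends one goal object per trial.  Every individual highlighting ``k``
carries a class label (target / non-target), the highlighted object
``o(k)``, its position in the stimulation sequence ``q(k)`` and the
aggregated position group (initial if ``q = 1``, else subsequent), plus
trial and repetition indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ContinuousRecording",
    "EventSchedule",
    "EpochSet",
    "SCHEDULE_COLUMNS",
    "INITIAL",
    "SUBSEQUENT",
]

INITIAL = "initial"
SUBSEQUENT = "subsequent"

#: required schedule columns (position_group is derived when absent)
SCHEDULE_COLUMNS = (
    "onset_s",
    "object",
    "trial",
    "repetition",
    "seq_position",
    "is_target",
)


@dataclass
class ContinuousRecording:
    """Continuous multi-channel EEG in microvolts."""

    data: np.ndarray  # channels x samples, uV
    rate: float  # samples / s
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match channel count")
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate


class EventSchedule:
    """Per-highlighting event table with validated paradigm invariants.

    Wraps a :class:`pandas.DataFrame` with columns ``onset_s`` (seconds),
    ``object`` (1-based id), ``trial``, ``repetition``, ``seq_position``
    (1-based position within the 3 s sequence), ``is_target`` (bool) and
    the derived ``position_group`` (initial / subsequent).
    """

    def __init__(self, frame: pd.DataFrame, ordered: bool = True):
        missing = [c for c in SCHEDULE_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"schedule is missing columns: {missing}")
        frame = frame.reset_index(drop=True).copy()
        frame["is_target"] = frame["is_target"].astype(bool)
        for col in ("object", "trial", "repetition", "seq_position"):
            frame[col] = frame[col].astype(int)
        frame["position_group"] = np.where(
            frame["seq_position"] == 1, INITIAL, SUBSEQUENT
        )
        onsets = frame["onset_s"].to_numpy(dtype=float)
        # ordered=False admits permuted in-memory views (e.g. reordered
        # epoch subsets); schedules read from disk stay strictly ordered
        if ordered and np.any(np.diff(onsets) <= 0):
            bad = np.nonzero(np.diff(onsets) <= 0)[0] + 1
            raise ValueError(
                f"onsets must be strictly increasing; violations at rows {bad[:5].tolist()}"
            )
        # a subset view (after event drops or filtering) may lose a trial's
        # target windows, but can never contain two distinct target objects
        for trial, grp in frame.groupby("trial"):
            targets = grp.loc[grp["is_target"], "object"].unique()
            if len(targets) > 1:
                raise ValueError(
                    f"trial {trial} has multiple target objects: "
                    f"{sorted(targets.tolist())}"
                )
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def onsets(self) -> np.ndarray:
        return self.frame["onset_s"].to_numpy(dtype=float)

    @property
    def labels(self) -> np.ndarray:
        """Boolean target labels y(k)."""
        return self.frame["is_target"].to_numpy()

    @property
    def objects(self) -> np.ndarray:
        return self.frame["object"].to_numpy()

    @property
    def trials(self) -> np.ndarray:
        return self.frame["trial"].to_numpy()

    def subclass_labels(self, definition: str = "object") -> np.ndarray:
        """Subclass index j(k) under a given subclass definition."""
        if definition == "object":
            return self.frame["object"].to_numpy()
        if definition == "position_group":
            return (self.frame["seq_position"].to_numpy() > 1).astype(int) + 1
        if definition == "position":
            return self.frame["seq_position"].to_numpy()
        raise ValueError(f"unknown subclass definition: {definition!r}")

    def subset(self, mask: np.ndarray) -> "EventSchedule":
        return EventSchedule(self.frame.loc[np.asarray(mask)].copy(), ordered=False)

    def target_object(self, trial: int) -> int:
        grp = self.frame[self.frame["trial"] == trial]
        targets = grp.loc[grp["is_target"], "object"]
        if targets.empty:
            raise ValueError(f"trial {trial} has no target windows")
        return int(targets.iloc[0])


@dataclass
class EpochSet:
    """Stimulus-locked windows aligned with their schedule rows.

    ``windows`` has shape (K, N_c, N_t) in uV; ``schedule`` has exactly K
    rows; ``rejected_mask`` marks artifact windows that must be excluded
    from all model fitting.
    """

    windows: np.ndarray
    schedule: EventSchedule
    rate: float
    rejected_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        if self.windows.ndim != 3:
            raise ValueError("windows must be K x N_c x N_t")
        if len(self.schedule) != self.windows.shape[0]:
            raise ValueError("schedule rows must align with windows")
        if self.rejected_mask is None:
            self.rejected_mask = np.zeros(self.windows.shape[0], dtype=bool)
        self.rejected_mask = np.asarray(self.rejected_mask, dtype=bool)

    @property
    def n_epochs(self) -> int:
        return self.windows.shape[0]

    @property
    def retained(self) -> np.ndarray:
        return ~self.rejected_mask

    def subset(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask)
        return EpochSet(
            windows=self.windows[mask],
            schedule=self.schedule.subset(mask),
            rate=self.rate,
            rejected_mask=self.rejected_mask[mask],
        )
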