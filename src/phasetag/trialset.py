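"""Containers for single-channel EEG trials aligned to stimulus onset."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np


@dataclass
class Trial:
    """One single-channel trial.

    ``samples`` is the voltage time series in microvolts; ``onset_index`` is
    the sample at which the modulated stimulus appeared (t = 0).  Everything
    before it is the zero-disparity pre-period used as baseline.
    """

    samples: np.ndarray
    fs: float
    onset_index: int
    condition: str = ""
    participant_id: str = ""
    good_flag: bool = True
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("Trial.samples must be one-dimensional")
        if not 0 <= self.onset_index < self.samples.size:
            raise ValueError("onset_index outside the trial")

    @property
    def pre_duration(self) -> float:
        return self.onset_index / self.fs

    @property
    def post_duration(self) -> float:
        return (self.samples.size - self.onset_index) / self.fs

    def copy(self) -> "Trial":
        return replace(self, samples=self.samples.copy(), meta=dict(self.meta))


@dataclass
class TrialSet:
    """A rectangular collection of onset-aligned trials.

    ``data`` has shape (n_trials, n_samples) and a single ``onset_index``
    shared by every row; per-trial labels live in ``participant_ids``,
    ``conditions`` and ``good_flags``.
    """

    data: np.ndarray
    fs: float
    onset_index: int
    conditions: np.ndarray
    participant_ids: np.ndarray
    good_flags: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        n = self.data.shape[0]
        self.conditions = _label_array(self.conditions, n, "conditions")
        self.participant_ids = _label_array(self.participant_ids, n, "participant_ids")
        self.good_flags = np.asarray(self.good_flags, dtype=bool)
        if self.good_flags.shape == ():
            self.good_flags = np.full(n, bool(self.good_flags))
        if self.good_flags.size != n:
            raise ValueError("good_flags length mismatch")
        if not 0 <= self.onset_index < self.data.shape[1]:
            raise ValueError("onset_index outside the trials")

    # ------------------------------------------------------------------
    @classmethod
    def from_trials(cls, trials: list[Trial], meta: dict | None = None) -> "TrialSet":
        """Stack trials, trimming to the common window around onset."""
        if not trials:
            raise ValueError("no trials to stack")
        fs = trials[0].fs
        if any(t.fs != fs for t in trials):
            raise ValueError("trials have mismatched sampling rates")
        pre = min(t.onset_index for t in trials)
        post = min(t.samples.size - t.onset_index for t in trials)
        data = np.stack(
            [t.samples[t.onset_index - pre : t.onset_index + post] for t in trials]
        )
        return cls(
            data=data,
            fs=fs,
            onset_index=pre,
            conditions=np.array([t.condition for t in trials]),
            participant_ids=np.array([t.participant_id for t in trials]),
            good_flags=np.array([t.good_flag for t in trials]),
            meta=dict(meta or {}),
        )

    # ------------------------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def pre_duration(self) -> float:
        return self.onset_index / self.fs

    @property
    def post_duration(self) -> float:
        return (self.n_samples - self.onset_index) / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to stimulus onset."""
        return (np.arange(self.n_samples) - self.onset_index) / self.fs

    def trial(self, i: int) -> Trial:
        return Trial(
            samples=self.data[i],
            fs=self.fs,
            onset_index=self.onset_index,
            condition=str(self.conditions[i]),
            participant_id=str(self.participant_ids[i]),
            good_flag=bool(self.good_flags[i]),
        )

    def select(self, mask: np.ndarray) -> "TrialSet":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            idx = mask
        else:
            idx = np.flatnonzero(mask)
        return TrialSet(
            data=self.data[idx],
            fs=self.fs,
            onset_index=self.onset_index,
            conditions=self.conditions[idx],
            participant_ids=self.participant_ids[idx],
            good_flags=self.good_flags[idx],
            meta=dict(self.meta),
        )

    def post_window(self, duration: float = 5.0) -> np.ndarray:
        """The first ``duration`` seconds after onset, as (n_trials, N)."""
        n = int(round(duration * self.fs))
        if self.onset_index + n > self.n_samples:
            raise ValueError(
                f"trials hold only {self.post_duration:.3f} s after onset, "
                f"need {duration} s"
            )
        return self.data[:, self.onset_index : self.onset_index + n]

    def copy(self) -> "TrialSet":
        return TrialSet(
            data=self.data.copy(),
            fs=self.fs,
            onset_index=self.onset_index,
            conditions=self.conditions.copy(),
            participant_ids=self.participant_ids.copy(),
            good_flags=self.good_flags.copy(),
            meta=dict(self.meta),
        )


def _label_array(values, n: int, name: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.shape == ():
        arr = np.full(n, arr.item())
    arr = np.array([str(v) for v in arr])
    if arr.size != n:
        raise ValueError(f"{name} length mismatch ({arr.size} != {n})")
    return arr
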