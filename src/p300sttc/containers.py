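"""In-memory containers shared across the pipeline.

Two containers travel through every stage: :class:`ContinuousRecording`
(channels x samples, with a stimulus event table) and :class:`EpochSet`
(trials x channels x time, with per-trial metadata).  Metadata is a pandas
DataFrame so it survives selection/concatenation without bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ContinuousRecording", "EpochSet", "TARGET", "NONTARGET"]

TARGET = "target"
NONTARGET = "nontarget"


@dataclass
class ContinuousRecording:
    """Continuous multi-channel EEG (microvolts) with stimulus events.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    sfreq : float
        Sampling rate in Hz.
    channels : list of str
        Channel labels, one per row of ``data``.
    events : list of (int, str)
        ``(onset_sample, code)`` pairs with ``code`` in {"target",
        "nontarget"}; onsets strictly increasing and inside the recording.
    """

    data: np.ndarray
    sfreq: float
    channels: list[str]
    events: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"channel count {self.data.shape[0]} != label count {len(self.channels)}"
            )
        onsets = [int(o) for o, _ in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")
        n = self.data.shape[1]
        if any(o < 0 or o >= n for o in onsets):
            raise ValueError("event onset outside the recording")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    def copy_with(self, data: np.ndarray) -> "ContinuousRecording":
        return ContinuousRecording(
            data=data, sfreq=self.sfreq, channels=list(self.channels), events=list(self.events)
        )


@dataclass
class EpochSet:
    """Epoched EEG: trials x channels x time, plus per-trial metadata.

    ``t_axis`` is in milliseconds relative to stimulus onset (0 = onset) and
    must be uniformly spaced at 1000/sfreq.  ``meta`` has one row per trial
    with at least columns ``subject_id``, ``group``, ``stimulus_code``,
    ``trial_index``.
    """

    data: np.ndarray
    channels: list[str]
    sfreq: float
    t_axis: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.t_axis = np.asarray(self.t_axis, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (trials x channels x time)")
        n_trials, n_ch, n_t = self.data.shape
        if n_ch != len(self.channels):
            raise ValueError("channel dimension does not match channel labels")
        if n_t != self.t_axis.size:
            raise ValueError("time dimension does not match t_axis")
        if len(self.meta) != n_trials:
            raise ValueError("meta rows must match trial count")
        if n_t > 1:
            dt = np.diff(self.t_axis)
            if not np.allclose(dt, 1000.0 / self.sfreq, atol=1e-6):
                raise ValueError("t_axis spacing inconsistent with sfreq")
        self.meta = self.meta.reset_index(drop=True)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def select(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask)
        return EpochSet(
            data=self.data[mask],
            channels=list(self.channels),
            sfreq=self.sfreq,
            t_axis=self.t_axis.copy(),
            meta=self.meta.loc[mask].reset_index(drop=True),
        )

    def select_code(self, code: str) -> "EpochSet":
        return self.select((self.meta["stimulus_code"] == code).to_numpy())

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError as err:
            raise KeyError(f"unknown channel {label!r}") from err

    @staticmethod
    def concatenate(parts: list["EpochSet"]) -> "EpochSet":
        if not parts:
            raise ValueError("nothing to concatenate")
        first = parts[0]
        for p in parts[1:]:
            if p.channels != first.channels or p.sfreq != first.sfreq:
                raise ValueError("incompatible EpochSets")
            if not np.allclose(p.t_axis, first.t_axis):
                raise ValueError("incompatible time axes")
        return EpochSet(
            data=np.concatenate([p.data for p in parts], axis=0),
            channels=list(first.channels),
            sfreq=first.sfreq,
            t_axis=first.t_axis.copy(),
            meta=pd.concat([p.meta for p in parts], ignore_index=True),
        )
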