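"""Continuous-to-epochs preprocessing.

Fixed stage order: band-pass (0.1-30 Hz, zero-phase Butterworth) ->
average reference -> artifact hook (pass-through by default) -> epoching
(-100..600 ms around stimulus onsets, half-open window) -> baseline
correction over [-100, 0) ms -> decimation to 250 Hz by sample keeping
(safe because the 30 Hz low-pass sits far below the 125 Hz post-decimation
Nyquist).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import signal

from .containers import ContinuousRecording, EpochSet

__all__ = [
    "bandpass",
    "average_reference",
    "remove_artifacts",
    "epoch",
    "baseline_correct",
    "decimate",
    "preprocess_recording",
    "preprocess_cohort",
]

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_MS = (-100.0, 600.0)
DEFAULT_BASELINE_MS = (-100.0, 0.0)


def bandpass(rec: ContinuousRecording, lo: float, hi: float, order: int = 4) -> ContinuousRecording:
    """Zero-phase Butterworth band-pass (applied forward-backward)."""
    nyq = rec.sfreq / 2.0
    if not (0 < lo < hi < nyq):
        raise ValueError(f"invalid band edges ({lo}, {hi}) for sfreq {rec.sfreq}")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=rec.sfreq, output="sos")
    out = signal.sosfiltfilt(sos, rec.data, axis=1)
    return rec.copy_with(out)


def average_reference(rec: ContinuousRecording) -> ContinuousRecording:
    """Re-reference to the channel mean; per-sample channel mean becomes 0."""
    if rec.n_channels < 2:
        raise ValueError("average reference requires at least 2 channels")
    out = rec.data - rec.data.mean(axis=0, keepdims=True)
    return rec.copy_with(out)


def remove_artifacts(rec: ContinuousRecording, method=None) -> ContinuousRecording:
    """Artifact-removal hook.

    Synthetic recordings carry no ocular/EMG artifacts, so the default is a
    pass-through.  A callable ``method(rec) -> ContinuousRecording`` can be
    plugged in (e.g. an ICA-based cleaner) for real data.
    """
    if method is None:
        return rec
    return method(rec)


def epoch(
    rec: ContinuousRecording,
    window_ms: tuple = DEFAULT_WINDOW_MS,
    codes=None,
    subject_id: str = "",
    group: str = "",
) -> EpochSet:
    """Cut epochs around stimulus onsets.

    The sample window is half-open: ``[onset + w0*fs, onset + w1*fs)`` — at
    1000 Hz the default -100..600 ms window yields exactly 700 samples.
    Events too close to the recording edges are dropped with a logged warning.
    """
    w0, w1 = window_ms
    if not w0 < w1:
        raise ValueError("empty epoch window")
    i0 = int(round(w0 * rec.sfreq / 1000.0))
    i1 = int(round(w1 * rec.sfreq / 1000.0))
    n_t = i1 - i0
    t_axis = (np.arange(i0, i1) / rec.sfreq) * 1000.0

    selected = [
        (onset, code)
        for onset, code in rec.events
        if codes is None or code in codes
    ]
    epochs, rows = [], []
    dropped = 0
    for k, (onset, code) in enumerate(selected):
        a, b = onset + i0, onset + i1
        if a < 0 or b > rec.n_samples:
            dropped += 1
            continue
        epochs.append(rec.data[:, a:b])
        rows.append(
            {"subject_id": subject_id, "group": group, "stimulus_code": code, "trial_index": k}
        )
    if dropped:
        logger.warning("dropped %d epoch(s) too close to the recording edge", dropped)
    data = np.stack(epochs, axis=0) if epochs else np.empty((0, rec.n_channels, n_t))
    meta = pd.DataFrame(rows, columns=["subject_id", "group", "stimulus_code", "trial_index"])
    return EpochSet(data=data, channels=list(rec.channels), sfreq=rec.sfreq, t_axis=t_axis, meta=meta)


def baseline_correct(ep: EpochSet, interval_ms: tuple = DEFAULT_BASELINE_MS) -> EpochSet:
    """Subtract the per-trial, per-channel mean over ``[b0, b1)`` ms."""
    b0, b1 = interval_ms
    mask = (ep.t_axis >= b0) & (ep.t_axis < b1)
    if not mask.any():
        raise ValueError("baseline interval does not intersect the epoch axis")
    base = ep.data[:, :, mask].mean(axis=2, keepdims=True)
    return EpochSet(
        data=ep.data - base,
        channels=list(ep.channels),
        sfreq=ep.sfreq,
        t_axis=ep.t_axis.copy(),
        meta=ep.meta.copy(),
    )


def decimate(ep: EpochSet, target_sfreq: float = 250.0) -> EpochSet:
    """Downsample by keeping every (sfreq/target)-th sample from the window start.

    Requires an integer ratio; anti-aliasing must already be ensured by the
    band-pass stage (checked by :func:`preprocess_recording`).
    """
    ratio = ep.sfreq / target_sfreq
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"sfreq {ep.sfreq} not divisible by target {target_sfreq}")
    r = int(round(ratio))
    return EpochSet(
        data=ep.data[:, :, ::r],
        channels=list(ep.channels),
        sfreq=target_sfreq,
        t_axis=ep.t_axis[::r].copy(),
        meta=ep.meta.copy(),
    )


def preprocess_recording(
    rec: ContinuousRecording,
    lo: float = 0.1,
    hi: float = 30.0,
    window_ms: tuple = DEFAULT_WINDOW_MS,
    baseline_ms: tuple = DEFAULT_BASELINE_MS,
    target_sfreq: float = 250.0,
    codes=None,
    subject_id: str = "",
    group: str = "",
    artifact_method=None,
) -> EpochSet:
    """Run the full stage order on one recording."""
    if hi >= target_sfreq / 2.0:
        raise ValueError(
            f"low-pass edge {hi} Hz must sit below the post-decimation Nyquist "
            f"{target_sfreq / 2.0} Hz"
        )
    rec = bandpass(rec, lo, hi)
    rec = average_reference(rec)
    rec = remove_artifacts(rec, artifact_method)
    ep = epoch(rec, window_ms, codes=codes, subject_id=subject_id, group=group)
    ep = baseline_correct(ep, baseline_ms)
    return decimate(ep, target_sfreq)


def preprocess_cohort(cohort, codes=None, **kwargs) -> EpochSet:
    """Preprocess a simulated cohort into one concatenated EpochSet."""
    parts = [
        preprocess_recording(rec, codes=codes, subject_id=sid, group=grp, **kwargs)
        for sid, grp, rec in cohort
    ]
    return EpochSet.concatenate(parts)
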