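"""Group-difference statistics on P300 epochs.

Trial-averaged per-subject waveforms feed three per-channel comparisons
between the PTSD and HC groups — window-mean amplitude, peak amplitude, and
peak latency, all inside the 250-500 ms P300 window — each an
independent-sample pooled-variance t-test with Cohen's d, Bonferroni-corrected
across channels.  Sign convention: PTSD minus HC, so a reduced PTSD amplitude
gives a negative t at fronto-central channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import TARGET, EpochSet

__all__ = [
    "PEAK_WINDOW_MS",
    "subject_average",
    "ttest_ind",
    "bonferroni",
    "peak_measures",
    "channel_stats",
    "topography_values",
]

PEAK_WINDOW_MS = (250.0, 500.0)


def subject_average(ep: EpochSet, code: str = TARGET):
    """Per-subject mean waveform over target trials.

    Returns ``(avg, subjects, groups)`` where ``avg`` is subjects x channels x
    time, and ``groups`` maps each subject to its group label.
    """
    sel = ep.select_code(code) if code is not None else ep
    subjects = list(dict.fromkeys(sel.meta["subject_id"]))  # insertion order
    if not subjects:
        raise ValueError("no trials to average")
    avg = np.empty((len(subjects), sel.data.shape[1], sel.data.shape[2]))
    groups = []
    for i, sid in enumerate(subjects):
        mask = (sel.meta["subject_id"] == sid).to_numpy()
        if mask.sum() == 0:
            raise ValueError(f"subject {sid} has no trials")
        avg[i] = sel.data[mask].mean(axis=0)
        groups.append(sel.meta.loc[mask, "group"].iloc[0])
    return avg, subjects, groups


def ttest_ind(a, b):
    """Independent two-sample pooled-variance t-test with Cohen's d.

    Returns ``(t, p, d)`` with d = (mean(a) - mean(b)) / pooled sd and the
    two-sided p from Student's t with n_a + n_b - 2 degrees of freedom.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    res = sps.ttest_ind(a, b, equal_var=True)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 <= 0:
        raise ValueError("zero pooled variance")
    d = (a.mean() - b.mean()) / np.sqrt(sp2)
    return float(res.statistic), float(res.pvalue), float(d)


def bonferroni(p_values) -> np.ndarray:
    """p' = min(1, p * n_tests) per value."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * p.size)


@dataclass
class PeakMeasures:
    """Peak amplitude (uV) and latency (ms) per subject x channel."""

    amplitude: np.ndarray  # subjects x channels
    latency: np.ndarray  # subjects x channels, ms
    window_ms: tuple
    subjects: list
    channels: list


def peak_measures(avg: np.ndarray, t_axis: np.ndarray, window_ms=PEAK_WINDOW_MS,
                  subjects=None, channels=None) -> PeakMeasures:
    """Maximum (positive deflection) and its latency inside the window.

    ``avg`` is subjects x channels x time; the window is closed; latency ties
    break toward the earliest sample (numpy argmax convention).
    """
    t_axis = np.asarray(t_axis, dtype=float)
    w0, w1 = window_ms
    mask = (t_axis >= w0) & (t_axis <= w1)
    if not mask.any():
        raise ValueError("peak window does not intersect the time axis")
    seg = avg[:, :, mask]
    idx = seg.argmax(axis=2)
    amplitude = np.take_along_axis(seg, idx[:, :, None], axis=2)[:, :, 0]
    latency = t_axis[mask][idx]
    return PeakMeasures(amplitude=amplitude, latency=latency, window_ms=tuple(window_ms),
                        subjects=subjects or [], channels=channels or [])


def channel_stats(ep: EpochSet, group_a: str = "PTSD", group_b: str = "HC",
                  window_ms=PEAK_WINDOW_MS, alpha: float = 0.05) -> pd.DataFrame:
    """Per-channel group comparison table.

    Columns mirror the statistic battery: mean-amplitude test (t_m, p_m, d_m),
    peak-amplitude test (p_a), peak-latency test (p_l); raw and
    Bonferroni-corrected p, with significance flags at ``alpha`` on the
    corrected values.  "Mean amplitude" is the per-subject mean of the
    trial-averaged waveform over the 250-500 ms window.
    """
    avg, subjects, groups = subject_average(ep)
    groups = np.asarray(groups)
    for g in (group_a, group_b):
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} needs at least 2 subjects")
    t_axis = ep.t_axis
    w0, w1 = window_ms
    wmask = (t_axis >= w0) & (t_axis <= w1)
    mean_amp = avg[:, :, wmask].mean(axis=2)  # subjects x channels
    peaks = peak_measures(avg, t_axis, window_ms)

    ia, ib = groups == group_a, groups == group_b
    rows = []
    for c, ch in enumerate(ep.channels):
        t_m, p_m, d_m = ttest_ind(mean_amp[ia, c], mean_amp[ib, c])
        _, p_a, _ = ttest_ind(peaks.amplitude[ia, c], peaks.amplitude[ib, c])
        _, p_l, _ = ttest_ind(peaks.latency[ia, c], peaks.latency[ib, c])
        rows.append({"channel": ch, "t_m": t_m, "p_m": p_m, "d_m": d_m,
                     "p_a": p_a, "p_l": p_l})
    table = pd.DataFrame(rows)
    for col in ("p_m", "p_a", "p_l"):
        table[f"{col}_corrected"] = bonferroni(table[col].to_numpy())
        table[f"significant_{col[2:]}"] = table[f"{col}_corrected"] < alpha
    return table


def topography_values(ep: EpochSet, group_a: str = "PTSD", group_b: str = "HC",
                      window_ms=PEAK_WINDOW_MS) -> pd.DataFrame:
    """Grand-average window-mean amplitude per channel per group.

    The difference column is HC minus PTSD (positive where the PTSD response
    is attenuated).
    """
    avg, _, groups = subject_average(ep)
    groups = np.asarray(groups)
    w0, w1 = window_ms
    wmask = (ep.t_axis >= w0) & (ep.t_axis <= w1)
    mean_amp = avg[:, :, wmask].mean(axis=2)
    val_a = mean_amp[groups == group_a].mean(axis=0)
    val_b = mean_amp[groups == group_b].mean(axis=0)
    return pd.DataFrame({
        "channel": ep.channels,
        group_a: val_a,
        group_b: val_b,
        "difference": val_b - val_a,
    })
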