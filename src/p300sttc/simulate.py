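"""Synthetic two-group oddball-ERP generator.

Emulates a 5x5 row/column oddball paradigm recorded from 10 channels of the
10-20 montage at 1000 Hz: each trial presents a target cue followed by a
stream of row/column flashes at a fixed interval, of which one carries the
target.  Target flashes evoke a P300 — modeled as a Gaussian bump whose
latency, amplitude and width are drawn per trial from group-specific
distributions — projected onto the scalp through a fronto-central topography.
Background activity is 1/f (pink) noise plus a 10 Hz alpha sinusoid.

The two default parameterizations encode the group effect of interest:
healthy controls (HC) peak near 312 ms with 5 uV at Fz, while the PTSD group
peaks near 415 ms with halved amplitude.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .containers import NONTARGET, TARGET, ContinuousRecording

__all__ = [
    "DEFAULT_CHANNELS",
    "DEFAULT_TOPOGRAPHY",
    "GroupParams",
    "ParadigmConfig",
    "NoiseConfig",
    "SimulationConfig",
    "p300_template",
    "pink_noise",
    "simulate_subject",
    "simulate_cohort",
]

DEFAULT_CHANNELS = ["Fp1", "Fp2", "Fz", "C3", "Cz", "C4", "Pz", "O1", "Oz", "O2"]

# Fronto-central dominance: the group difference is strongest at Fz/Cz.
DEFAULT_TOPOGRAPHY = {
    "Fz": 1.0,
    "Cz": 0.9,
    "C3": 0.8,
    "C4": 0.8,
    "Pz": 0.6,
    "Fp1": 0.4,
    "Fp2": 0.4,
    "O1": 0.3,
    "Oz": 0.3,
    "O2": 0.3,
}


@dataclass
class ParadigmConfig:
    """Oddball schedule: runs x blocks x trials, flashes every 0.5 s."""

    runs: int = 2
    blocks_per_run: int = 2
    trials_per_block: int = 25
    flash_interval: float = 0.5
    target_cue_duration: float = 1.0


@dataclass
class GroupParams:
    """Per-group P300 distribution.

    Latency/width in ms, amplitude in uV.  ``p300_width_mean`` is the Gaussian
    sigma of the bump (45 ms sigma gives a ~106 ms FWHM deflection).  Each
    subject first draws trait means around the group means (the ``between``
    sds: stable individual differences), then every target trial jitters
    around the subject's traits (the plain sds: within-subject variability).
    """

    p300_peak_latency_mean: float
    p300_peak_latency_sd: float = 20.0
    p300_amplitude_mean: float = 5.0
    p300_amplitude_sd: float = 1.0
    p300_width_mean: float = 45.0
    p300_width_sd: float = 5.0
    p300_latency_between_sd: float = 25.0
    p300_amplitude_between_sd: float = 1.0


@dataclass
class NoiseConfig:
    """Background EEG model: pink noise at ``noise_rms`` plus a 10 Hz sinusoid
    of amplitude ``alpha_power`` with random per-channel phase."""

    pink_slope: float = 1.0
    noise_rms: float = 4.0
    alpha_power: float = 2.0


def _default_group_params() -> dict:
    return {
        "HC": GroupParams(p300_peak_latency_mean=312.0, p300_amplitude_mean=5.0),
        "PTSD": GroupParams(p300_peak_latency_mean=415.0, p300_amplitude_mean=2.5),
    }


@dataclass
class SimulationConfig:
    n_subjects_per_group: int = 12
    channels: list[str] = field(default_factory=lambda: list(DEFAULT_CHANNELS))
    sfreq_raw: float = 1000.0
    paradigm: ParadigmConfig = field(default_factory=ParadigmConfig)
    group_params: dict = field(default_factory=_default_group_params)
    topography: dict = field(default_factory=lambda: dict(DEFAULT_TOPOGRAPHY))
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    nontarget_flashes_per_target: int = 8
    # lognormal sigma of stable per-subject, per-channel gain factors
    # (electrode impedance / anatomy differences)
    subject_gain_sd: float = 0.2
    seed: int = 0
    # epoch window the downstream pipeline will use, for spacing validation
    epoch_window_ms: tuple = (-100.0, 600.0)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_subjects_per_group < 1:
            raise ValueError("n_subjects_per_group must be >= 1")
        if self.paradigm.trials_per_block <= 0:
            raise ValueError("trials_per_block must be positive")
        if self.paradigm.flash_interval <= 0:
            raise ValueError("flash_interval must be positive")
        for ch, g in self.topography.items():
            if not 0.0 <= g <= 1.0:
                raise ValueError(f"topography gain for {ch} outside [0, 1]")
        for ch in self.channels:
            if ch not in self.topography:
                raise ValueError(f"channel {ch} missing from topography")
        w0, w1 = self.epoch_window_ms
        for name, gp in self.group_params.items():
            if not w0 < gp.p300_peak_latency_mean < w1:
                raise ValueError(f"{name} latency mean outside the epoch window")
            for sd in (gp.p300_peak_latency_sd, gp.p300_amplitude_sd, gp.p300_width_sd,
                       gp.p300_latency_between_sd, gp.p300_amplitude_between_sd):
                if sd < 0:
                    raise ValueError("standard deviations must be >= 0")
            if gp.p300_width_mean <= 0:
                raise ValueError("p300_width_mean must be positive")
        # successive target events must be separated by more than the epoch span
        min_target_gap = self.paradigm.target_cue_duration + self.paradigm.flash_interval
        if min_target_gap * 1000.0 <= (w1 - w0):
            raise ValueError(
                "epoch window exceeds the minimum spacing between target events"
            )

    def noiseless(self) -> "SimulationConfig":
        """Copy with zero background noise and zero per-trial jitter."""
        gp = {
            name: replace(g, p300_peak_latency_sd=0.0, p300_amplitude_sd=0.0,
                          p300_width_sd=0.0, p300_latency_between_sd=0.0,
                          p300_amplitude_between_sd=0.0)
            for name, g in self.group_params.items()
        }
        return replace(
            self,
            group_params=gp,
            subject_gain_sd=0.0,
            noise=NoiseConfig(pink_slope=self.noise.pink_slope, noise_rms=0.0, alpha_power=0.0),
        )

    # -- JSON round trip (provenance sidecars, CLI configs) ------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["epoch_window_ms"] = list(d["epoch_window_ms"])
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "paradigm" in d and isinstance(d["paradigm"], dict):
            d["paradigm"] = ParadigmConfig(**d["paradigm"])
        if "noise" in d and isinstance(d["noise"], dict):
            d["noise"] = NoiseConfig(**d["noise"])
        if "group_params" in d:
            d["group_params"] = {
                k: (GroupParams(**v) if isinstance(v, dict) else v)
                for k, v in d["group_params"].items()
            }
        if "epoch_window_ms" in d:
            d["epoch_window_ms"] = tuple(d["epoch_window_ms"])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def p300_template(latency: float, amplitude: float, width: float, t_axis: np.ndarray) -> np.ndarray:
    """Gaussian-bump P300 surrogate.

    Parameters are in ms (latency, width = Gaussian sigma) and uV (amplitude);
    ``t_axis`` is a time axis in ms.  Returns
    ``amplitude * exp(-(t - latency)^2 / (2 width^2))``.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    t = np.asarray(t_axis, dtype=float)
    return amplitude * np.exp(-((t - latency) ** 2) / (2.0 * width**2))


def pink_noise(rng: np.random.Generator, n_samples: int, slope: float = 1.0) -> np.ndarray:
    """Unit-RMS 1/f^slope noise via spectral shaping of white noise."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-slope / 2.0)
    scale[0] = 0.0  # no DC
    x = np.fft.irfft(spec * scale, n=n_samples)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _event_schedule(cfg: SimulationConfig, rng: np.random.Generator):
    """Flash onsets for one subject.

    Each trial: a target cue period (no flashes), then
    ``nontarget_flashes_per_target + 1`` flashes at ``flash_interval`` spacing,
    one of which (seeded-random position) is the target.
    """
    p = cfg.paradigm
    sf = cfg.sfreq_raw
    n_flashes = cfg.nontarget_flashes_per_target + 1
    events: list[tuple[int, str]] = []
    t = 1.0  # settle-in before the first trial
    for _run in range(p.runs):
        for _block in range(p.blocks_per_run):
            for _trial in range(p.trials_per_block):
                t += p.target_cue_duration
                target_pos = int(rng.integers(0, n_flashes))
                for k in range(n_flashes):
                    onset = int(round((t + k * p.flash_interval) * sf))
                    code = TARGET if k == target_pos else NONTARGET
                    events.append((onset, code))
                t += n_flashes * p.flash_interval
        t += 2.0  # inter-block rest
    return events, t + 1.0


def simulate_subject(
    cfg: SimulationConfig, group: str, subject_seed: int
) -> ContinuousRecording:
    """Simulate one subject's continuous recording.

    Reproducible from ``(cfg.seed, subject_seed)``; target flashes carry the
    P300 template with per-trial latency/amplitude/width drawn from the
    group's distribution, scaled per channel by the topography gain.
    """
    if group not in cfg.group_params:
        raise KeyError(f"unknown group {group!r}")
    gp: GroupParams = cfg.group_params[group]
    rng = np.random.default_rng([int(cfg.seed) & 0x7FFFFFFF, int(subject_seed) & 0x7FFFFFFF])

    events, duration_s = _event_schedule(cfg, rng)
    n_samples = int(round(duration_s * cfg.sfreq_raw))
    n_ch = len(cfg.channels)
    data = np.zeros((n_ch, n_samples))

    # stable per-subject channel gains (impedance/anatomy differences)
    if cfg.subject_gain_sd > 0:
        ch_gain = np.exp(cfg.subject_gain_sd * rng.standard_normal(n_ch))
    else:
        ch_gain = np.ones(n_ch)

    if cfg.noise.noise_rms > 0:
        for c in range(n_ch):
            data[c] = cfg.noise.noise_rms * pink_noise(rng, n_samples, cfg.noise.pink_slope)
    if cfg.noise.alpha_power > 0:
        t_sec = np.arange(n_samples) / cfg.sfreq_raw
        for c in range(n_ch):
            phase = rng.uniform(0, 2 * np.pi)
            data[c] += cfg.noise.alpha_power * np.sin(2 * np.pi * 10.0 * t_sec + phase)
    data *= ch_gain[:, None]

    gains = ch_gain * np.array([cfg.topography[ch] for ch in cfg.channels])
    # stable subject traits, then per-trial jitter around them
    subj_latency = (gp.p300_peak_latency_mean
                    + gp.p300_latency_between_sd * rng.standard_normal())
    subj_amplitude = (gp.p300_amplitude_mean
                      + gp.p300_amplitude_between_sd * rng.standard_normal())
    # template support: +-5 sigma around the drawn latency
    for onset, code in events:
        if code != TARGET:
            continue
        latency = subj_latency + gp.p300_peak_latency_sd * rng.standard_normal()
        amplitude = subj_amplitude + gp.p300_amplitude_sd * rng.standard_normal()
        width = max(gp.p300_width_mean + gp.p300_width_sd * rng.standard_normal(), 5.0)
        half_ms = 5.0 * width
        i0 = max(onset + int(np.floor((latency - half_ms) * cfg.sfreq_raw / 1000.0)), 0)
        i1 = min(onset + int(np.ceil((latency + half_ms) * cfg.sfreq_raw / 1000.0)) + 1, n_samples)
        t_ms = (np.arange(i0, i1) - onset) * 1000.0 / cfg.sfreq_raw
        bump = p300_template(latency, amplitude, width, t_ms)
        data[:, i0:i1] += gains[:, None] * bump[None, :]

    return ContinuousRecording(data=data, sfreq=cfg.sfreq_raw, channels=list(cfg.channels), events=events)


def simulate_cohort(cfg: SimulationConfig):
    """Simulate the full two-group cohort.

    Returns a list of ``(subject_id, group, ContinuousRecording)`` with
    ``2 * n_subjects_per_group`` entries, balanced across groups.
    """
    out = []
    groups = sorted(cfg.group_params)
    for gi, group in enumerate(groups):
        for s in range(cfg.n_subjects_per_group):
            subject_id = f"{group}{s + 1:02d}"
            subject_seed = gi * 10_000 + s
            out.append((subject_id, group, simulate_subject(cfg, group, subject_seed)))
    return out
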