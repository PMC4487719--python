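"""Seeded synthetic cue-based EEG/force recordings.

Emulates a cue-paced ankle-dorsiflexion protocol: per task, repeated trials
in which a movement-related cortical potential (MRCP) — a slow negativity
beginning ~2 s before movement onset — is embedded in 1/f-plus-alpha
background EEG on a ten-channel 10-20 montage, together with a noisy force
(torque) trace that ramps to the task's target contraction level.

Two tasks are modelled:

``f60``
    fast ramp reaching 60% of maximum voluntary contraction (MVC) in 0.5 s.
``s20``
    slow ramp reaching 20% MVC in 3 s.

All randomness flows from ``SimulationConfig.seed``; identical config gives a
byte-identical :class:`Recording`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

#: Fixed channel order of the montage. FP1 carries EOG and no MRCP.
CHANNELS: tuple[str, ...] = (
    "FP1", "F3", "Fz", "F4", "C3", "Cz", "C4", "P3", "Pz", "P4",
)

#: task-id -> (target force as fraction of MVC, ramp duration in s)
TASKS: dict[str, tuple[float, float]] = {
    "f60": (0.60, 0.5),
    "s20": (0.20, 3.0),
}

#: How long the target force level is held before release (s).
PLATEAU_S = 0.5
#: Linear release back to baseline after the plateau (s).
RELEASE_S = 0.5

GROUPS = ("real", "imaginary", "attempted")


def _default_gains() -> dict[str, float]:
    # MRCP scalp gain peaked at Cz; the surrounding ring at 0.4 so the large
    # Laplacian keeps a net MRCP of 1.0 - 0.4 = 0.6; FP1 (EOG site) gets none.
    gains = {ch: 0.4 for ch in CHANNELS}
    gains["Cz"] = 1.0
    gains["FP1"] = 0.0
    return gains


@dataclass
class SimulationConfig:
    """Parameters of the synthetic protocol.

    Defaults reproduce the study conditions: 2 x 50 cue-based trials, EEG at
    500 Hz on the ten-channel montage, force at 2000 Hz, and an MRCP rising
    over the 2 s preceding movement onset.
    """

    n_trials_per_task: int = 50
    tasks: tuple[str, ...] = ("f60", "s20")
    fs_eeg: float = 500.0
    fs_force: float = 2000.0
    #: MRCP peak (µV) at the vertex; negative by convention.
    mrcp_peak_amplitude: float = -10.0
    #: The negativity starts this many seconds before movement onset.
    mrcp_rise_start: float = 2.0
    #: Post-onset recovery time back to baseline (s); epochs end at onset,
    #: so only the pre-onset ramp shape matters downstream.
    mrcp_recovery: float = 1.0
    #: Standard deviation of the 1/f background on each channel (µV).
    background_pink_sd: float = 2.0
    #: Amplitude of the occipito-parietal alpha-like sinusoid (µV).
    alpha_amplitude: float = 1.0
    alpha_freq: float = 10.0
    #: Per-channel MRCP scaling (unitless), peaked at Cz.
    channel_gains: dict[str, float] = field(default_factory=_default_gains)
    #: Cue-to-cue spacing (s); must leave room for the noise window
    #: (-5..-3 s) and the force baseline window (-4..-2 s before the cue).
    inter_trial_interval: float = 12.0
    #: Force sensor noise, white Gaussian, as a fraction of MVC.
    force_noise_sd: float = 0.001
    #: Reaction-time jitter: true onset = cue + U(0, onset_jitter_max) s.
    onset_jitter_max: float = 0.3
    #: Optional mains interference (µV); off by default (no notch is applied
    #: anywhere in the pipeline).
    line_noise_amplitude: float = 0.0
    line_noise_freq: float = 50.0
    seed: int = 0

    def validate(self) -> None:
        if self.fs_eeg <= 200.0:
            raise ValueError(
                "fs_eeg must exceed 200 Hz so the 30-100 Hz band is representable"
            )
        if self.inter_trial_interval < 10.0:
            raise ValueError(
                "inter_trial_interval must be >= 10 s so noise and baseline "
                "windows do not overlap the previous trial"
            )
        if self.mrcp_rise_start <= 0:
            raise ValueError("mrcp_rise_start must be positive")
        unknown = set(self.channel_gains) - set(CHANNELS)
        if unknown:
            raise ValueError(f"channel_gains for unknown channels: {sorted(unknown)}")
        for task in self.tasks:
            if task not in TASKS:
                raise ValueError(f"unknown task {task!r}; expected one of {sorted(TASKS)}")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class Recording:
    """One subject's continuous recording plus trial metadata.

    ``true_onsets`` is simulation ground truth and is absent (None) for
    recordings loaded from user files.
    """

    eeg: np.ndarray            # (n_channels, n_samples), µV
    channels: tuple[str, ...]
    fs_eeg: float
    force: np.ndarray          # (n_force_samples,), fraction of MVC
    fs_force: float
    cue_times: np.ndarray      # (n_trials,), s, = cued task onsets
    task_labels: list[str]
    true_onsets: np.ndarray | None
    group: str                 # one of GROUPS
    subject_id: str = "sim"

    def __post_init__(self) -> None:
        if len(self.cue_times) != len(self.task_labels):
            raise ValueError("cue_times and task_labels must have equal length")
        if np.any(np.diff(self.cue_times) <= 0):
            raise ValueError("cue_times must be strictly increasing")

    @property
    def duration(self) -> float:
        return self.eeg.shape[1] / self.fs_eeg


def mrcp_waveform(t_rel, cfg: SimulationConfig) -> np.ndarray:
    """MRCP amplitude (µV) at time ``t_rel`` seconds relative to onset.

    Zero before the rise starts, a half-cosine ramp down to the peak at the
    onset, then a half-cosine recovery back to zero. Vectorised over t_rel.
    """
    t = np.asarray(t_rel, dtype=float)
    out = np.zeros_like(t)
    rise = cfg.mrcp_rise_start
    peak = cfg.mrcp_peak_amplitude
    m = (t > -rise) & (t <= 0)
    out[m] = peak * 0.5 * (1.0 - np.cos(np.pi * (t[m] + rise) / rise))
    rec = cfg.mrcp_recovery
    m = (t > 0) & (t < rec)
    out[m] = peak * 0.5 * (1.0 + np.cos(np.pi * t[m] / rec))
    return out if out.ndim else float(out)


def generate_background(n_samples: int, cfg: SimulationConfig,
                        rng: np.random.Generator) -> np.ndarray:
    """Background EEG: 1/f ("pink") noise plus an alpha-band sinusoid.

    Pink noise is synthesised by spectral shaping of white Gaussian noise
    (amplitude ∝ 1/sqrt(f), DC bin zeroed) and rescaled so its sample
    standard deviation equals ``background_pink_sd`` exactly; the sinusoid
    has amplitude ``alpha_amplitude`` and a random phase.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    out = np.zeros(n_samples)
    # Draw order is fixed so results are reproducible regardless of which
    # components are switched off.
    white = rng.standard_normal(n_samples)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    if cfg.background_pink_sd > 0:
        spec = np.fft.rfft(white)
        f = np.fft.rfftfreq(n_samples, d=1.0 / cfg.fs_eeg)
        shaping = np.zeros_like(f)
        shaping[1:] = 1.0 / np.sqrt(f[1:])
        pink = np.fft.irfft(spec * shaping, n=n_samples)
        sd = pink.std()
        if sd > 0:
            out += pink * (cfg.background_pink_sd / sd)
    if cfg.alpha_amplitude > 0:
        t = np.arange(n_samples) / cfg.fs_eeg
        out += cfg.alpha_amplitude * np.sin(2.0 * np.pi * cfg.alpha_freq * t + phase)
    if cfg.line_noise_amplitude > 0:
        t = np.arange(n_samples) / cfg.fs_eeg
        out += cfg.line_noise_amplitude * np.sin(
            2.0 * np.pi * cfg.line_noise_freq * t + phase
        )
    return out


def _force_shape(task: str, t_rel: np.ndarray) -> np.ndarray:
    """Noiseless force profile (fraction of MVC) vs time relative to onset.

    Linear ramp to the task target over the task's ramp duration — the shape
    of the visual cue subjects track — held for ``PLATEAU_S`` then released
    linearly over ``RELEASE_S``.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {sorted(TASKS)}")
    target, ramp = TASKS[task]
    t = np.asarray(t_rel, dtype=float)
    out = np.zeros_like(t)
    m = (t >= 0) & (t < ramp)
    out[m] = target * t[m] / ramp
    m = (t >= ramp) & (t < ramp + PLATEAU_S)
    out[m] = target
    m = (t >= ramp + PLATEAU_S) & (t < ramp + PLATEAU_S + RELEASE_S)
    out[m] = target * (1.0 - (t[m] - ramp - PLATEAU_S) / RELEASE_S)
    return out


def generate_force_trace(task: str, onset: float, cfg: SimulationConfig,
                         rng: np.random.Generator, n_samples: int,
                         t0: float = 0.0) -> np.ndarray:
    """Force series of ``n_samples`` at ``fs_force`` starting at time ``t0``.

    Baseline 0 before ``onset``; ramp/plateau/release per the task profile;
    additive white Gaussian noise of sd ``force_noise_sd``.
    """
    t = t0 + np.arange(n_samples) / cfg.fs_force
    trace = _force_shape(task, t - onset)
    if cfg.force_noise_sd > 0:
        trace = trace + rng.normal(0.0, cfg.force_noise_sd, n_samples)
    return trace


def generate_recording(cfg: SimulationConfig, group: str = "real",
                       subject_id: str = "sim") -> Recording:
    """Simulate one subject's full session.

    Trials are laid out at ``inter_trial_interval`` spacing with tasks in
    randomised block order (all repetitions of one task, then the other).
    For ``real``/``attempted`` movements the true onset lags the cue by a
    uniform 0..``onset_jitter_max`` s reaction delay and the force trace
    contains the task ramp; for ``imaginary`` movements the true onset
    equals the cue and the force stays at baseline.
    """
    cfg.validate()
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    rng = np.random.default_rng(cfg.seed)

    task_order = list(cfg.tasks)
    rng.shuffle(task_order)
    task_labels = [t for t in task_order for _ in range(cfg.n_trials_per_task)]
    n_trials = len(task_labels)

    iti = cfg.inter_trial_interval
    cue_times = iti * (1.0 + np.arange(n_trials))
    duration = iti * (n_trials + 1)
    n_eeg = int(round(duration * cfg.fs_eeg))
    n_force = int(round(duration * cfg.fs_force))

    if group == "imaginary":
        onsets = cue_times.copy()
        rng.uniform(0.0, cfg.onset_jitter_max, n_trials)  # keep draw order fixed
    else:
        onsets = cue_times + rng.uniform(0.0, cfg.onset_jitter_max, n_trials)

    # EEG: per-channel background plus the gain-scaled MRCP at each onset.
    eeg = np.empty((len(CHANNELS), n_eeg))
    for i in range(len(CHANNELS)):
        eeg[i] = generate_background(n_eeg, cfg, rng)
    t_eeg = np.arange(n_eeg) / cfg.fs_eeg
    mrcp_sum = np.zeros(n_eeg)
    for onset in onsets:
        lo = max(0, int((onset - cfg.mrcp_rise_start - 0.1) * cfg.fs_eeg))
        hi = min(n_eeg, int((onset + cfg.mrcp_recovery + 0.1) * cfg.fs_eeg))
        mrcp_sum[lo:hi] += mrcp_waveform(t_eeg[lo:hi] - onset, cfg)
    for i, ch in enumerate(CHANNELS):
        gain = cfg.channel_gains.get(ch, 0.0)
        if gain:
            eeg[i] += gain * mrcp_sum

    # Force: sensor noise everywhere; task ramps only when movement is real.
    force = (rng.normal(0.0, cfg.force_noise_sd, n_force)
             if cfg.force_noise_sd > 0 else np.zeros(n_force))
    if group != "imaginary":
        t_force = np.arange(n_force) / cfg.fs_force
        for onset, task in zip(onsets, task_labels):
            lo = max(0, int(onset * cfg.fs_force) - 1)
            _, ramp = TASKS[task]
            hi = min(n_force, int((onset + ramp + PLATEAU_S + RELEASE_S + 0.1)
                                  * cfg.fs_force))
            force[lo:hi] += _force_shape(task, t_force[lo:hi] - onset)

    return Recording(
        eeg=eeg, channels=CHANNELS, fs_eeg=cfg.fs_eeg,
        force=force, fs_force=cfg.fs_force,
        cue_times=cue_times, task_labels=task_labels,
        true_onsets=onsets, group=group, subject_id=subject_id,
    )
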