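"""Force-based movement-onset detection and epoch extraction.

Movement onset is read off the force trace: the first sample at or after the
cue for which every sample of the following 200 ms window strictly exceeds
the pre-cue baseline (the mean force 2–4 s before the cue), the window
advancing one sample at a time. Signal ("movement") epochs cover the 2 s up
to the onset; noise epochs cover 5–3 s before it. Both are cut from the
preprocessed surrogate channel.

Windows are half-open ``[start, end)`` with 0-based indices, so a 2 s epoch
at 500 Hz is exactly 1000 samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .preprocess import SurrogatePair

logger = logging.getLogger(__name__)

EPOCH_DURATION_S = 2.0
#: Movement epoch: [onset - 2 s, onset). Noise epoch: [onset - 5 s, onset - 3 s).
NOISE_OFFSET_S = 5.0
ONSET_WINDOW_S = 0.2
BASELINE_WINDOW_S = (4.0, 2.0)   # seconds before the cue
ONSET_SEARCH_S = 5.0


class OnsetNotFoundError(RuntimeError):
    """No qualifying onset window inside the search range."""


@dataclass
class Epoch:
    """A fixed 2 s surrogate-channel window with its class label."""

    samples: np.ndarray
    label: str        # "movement" | "noise"
    task: str         # f60 | s20; for noise epochs the parent trial's task
    t0: float         # epoch start, seconds on the recording clock
    path: str         # "temporal" | "spectral"
    fs: float
    subject_id: str = "sim"

    def __post_init__(self) -> None:
        expected = int(round(EPOCH_DURATION_S * self.fs))
        if len(self.samples) != expected:
            raise ValueError(
                f"epoch must be {expected} samples at {self.fs} Hz, "
                f"got {len(self.samples)}"
            )
        if self.label not in ("movement", "noise"):
            raise ValueError(f"unknown epoch label {self.label!r}")


def detect_force_onset(force: np.ndarray, fs: float, cue_time: float,
                       t0: float = 0.0, baseline_margin_sd: float = 0.0) -> float:
    """Time (s) of the first 200 ms window entirely above the baseline.

    ``baseline_margin_sd`` optionally raises the threshold by that multiple
    of the baseline window's standard deviation (0 = the literal rule:
    strictly above the baseline mean).
    """
    force = np.asarray(force, dtype=float)
    cue_idx = int(round((cue_time - t0) * fs))
    b_lo = int(round((cue_time - BASELINE_WINDOW_S[0] - t0) * fs))
    b_hi = int(round((cue_time - BASELINE_WINDOW_S[1] - t0) * fs))
    if b_lo < 0 or b_hi <= b_lo:
        raise ValueError("force trace does not cover the baseline window")
    baseline = force[b_lo:b_hi]
    threshold = baseline.mean()
    if baseline_margin_sd:
        threshold += baseline_margin_sd * baseline.std()

    w = int(round(ONSET_WINDOW_S * fs))
    stop = min(len(force) - w + 1, cue_idx + int(round(ONSET_SEARCH_S * fs)))
    if cue_idx >= stop:
        raise OnsetNotFoundError("search range empty")
    windows = np.lib.stride_tricks.sliding_window_view(force[cue_idx:stop + w - 1], w)
    ok = np.flatnonzero(windows.min(axis=1) > threshold)
    if len(ok) == 0:
        raise OnsetNotFoundError(
            f"no 200 ms window above baseline within {ONSET_SEARCH_S} s of the cue"
        )
    return t0 + (cue_idx + int(ok[0])) / fs


@dataclass
class ResolvedOnsets:
    """Per-trial onsets after force processing; indices refer to the
    recording's trial list."""

    onsets: list[float]
    trial_indices: list[int]
    dropped: list[int]       # trials with no detectable onset
    flagged: list[int]       # imagery trials whose force shows a movement


def resolve_onsets(recording, group: str | None = None,
                   imagery_force_threshold: float = 0.05,
                   baseline_margin_sd: float = 0.0) -> ResolvedOnsets:
    """Determine each trial's onset according to the subject group.

    For executed movements (``real``/``attempted``) the onset comes from
    :func:`detect_force_onset`; trials where no onset is found are dropped
    and logged. For ``imaginary`` movements the cue-defined task onset is
    used directly and a guard flags trials whose force rises more than
    ``imagery_force_threshold`` (fraction of MVC) above baseline.
    """
    group = group or recording.group
    onsets: list[float] = []
    kept: list[int] = []
    dropped: list[int] = []
    flagged: list[int] = []
    fs = recording.fs_force
    for i, cue in enumerate(recording.cue_times):
        if group == "imaginary":
            b_lo = int(round((cue - BASELINE_WINDOW_S[0]) * fs))
            b_hi = int(round((cue - BASELINE_WINDOW_S[1]) * fs))
            s_hi = min(len(recording.force),
                       int(round((cue + ONSET_SEARCH_S) * fs)))
            baseline = recording.force[max(b_lo, 0):b_hi].mean()
            peak = recording.force[b_hi:s_hi].max()
            if peak - baseline > imagery_force_threshold:
                flagged.append(i)
                logger.warning(
                    "subject %s trial %d: imagery trial shows force %.3f MVC "
                    "above baseline", recording.subject_id, i, peak - baseline)
            onsets.append(float(cue))
            kept.append(i)
        else:
            try:
                onsets.append(detect_force_onset(
                    recording.force, fs, float(cue),
                    baseline_margin_sd=baseline_margin_sd))
                kept.append(i)
            except OnsetNotFoundError as exc:
                dropped.append(i)
                logger.warning("subject %s trial %d dropped: %s",
                               recording.subject_id, i, exc)
    return ResolvedOnsets(onsets=onsets, trial_indices=kept,
                          dropped=dropped, flagged=flagged)


def extract_epochs(surrogate: SurrogatePair, onsets, tasks, path: str,
                   subject_id: str = "sim") -> list[Epoch]:
    """Cut one movement and one noise epoch per trial from the given path.

    Movement epoch: ``[onset - 2 s, onset)``; noise epoch:
    ``[onset - 5 s, onset - 3 s)``. Start index = ``round(t * fs)``. Trials
    whose windows fall outside the recording are dropped and logged.
    """
    if path not in ("temporal", "spectral"):
        raise ValueError(f"unknown path {path!r}")
    series = surrogate.temporal_path if path == "temporal" else surrogate.spectral_path
    fs = surrogate.fs
    n = int(round(EPOCH_DURATION_S * fs))
    out: list[Epoch] = []
    for onset, task in zip(onsets, tasks):
        mov_start = int(round((onset - EPOCH_DURATION_S) * fs))
        noise_start = int(round((onset - NOISE_OFFSET_S) * fs))
        if noise_start < 0 or mov_start + n > len(series):
            logger.warning("subject %s: trial at onset %.2f s dropped "
                           "(epoch window out of range)", subject_id, onset)
            continue
        out.append(Epoch(series[mov_start:mov_start + n].copy(), "movement",
                         task, mov_start / fs, path, fs, subject_id))
        out.append(Epoch(series[noise_start:noise_start + n].copy(), "noise",
                         task, noise_start / fs, path, fs, subject_id))
    return out
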