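"""Temporal filtering and Laplacian spatial reduction to a surrogate channel.

All downstream stages operate on a single surrogate channel: the large
Laplacian combination of the nine scalp channels (FP1 is excluded as the EOG
site). Two temporally filtered versions of the surrogate are kept:

* *temporal path* — 2nd-order Butterworth band-pass 0.05–10 Hz, applied
  forward and reverse (zero phase), isolating the MRCP;
* *spectral path* — 2nd-order Butterworth high-pass 0.05 Hz, forward and
  reverse, keeping the full EEG band for power-spectral features.

The spatial filter is applied first and the temporal filters act on the
single surrogate series; by linearity this equals filtering every channel
then combining, at a ninth of the cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

#: Channels entering the Laplacian: Cz plus its ring of eight.
LAPLACIAN_CENTER = "Cz"
LAPLACIAN_RING = ("F3", "Fz", "F4", "C3", "C4", "P3", "Pz", "P4")

BANDPASS_LO = 0.05
BANDPASS_HI = 10.0
HIGHPASS_CUTOFF = 0.05
FILTER_ORDER = 2


@dataclass
class SurrogatePair:
    """The two filtered versions of the Laplacian surrogate channel."""

    temporal_path: np.ndarray   # band-passed 0.05-10 Hz (µV)
    spectral_path: np.ndarray   # high-passed 0.05 Hz (µV)
    fs: float

    def __post_init__(self) -> None:
        if len(self.temporal_path) != len(self.spectral_path):
            raise ValueError("temporal and spectral paths must have equal length")


def bandpass_mrcp(x: np.ndarray, fs: float, lo: float = BANDPASS_LO,
                  hi: float = BANDPASS_HI, order: int = FILTER_ORDER) -> np.ndarray:
    """Zero-phase 2nd-order Butterworth band-pass (0.05–10 Hz by default).

    Applied forward then reverse (``sosfiltfilt``), so the net magnitude
    response is the squared Butterworth magnitude and the phase is zero.
    Output length equals input length.
    """
    if fs <= 2 * hi:
        raise ValueError(f"sampling rate {fs} Hz too low for a {hi} Hz corner")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float))


def highpass_spectral(x: np.ndarray, fs: float, cutoff: float = HIGHPASS_CUTOFF,
                      order: int = FILTER_ORDER) -> np.ndarray:
    """Zero-phase 2nd-order Butterworth high-pass (0.05 Hz): removes DC,
    keeps everything up to Nyquist."""
    sos = signal.butter(order, cutoff, btype="highpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float))


def laplacian_surrogate(eeg: np.ndarray, channel_names) -> np.ndarray:
    """Large Laplacian surrogate: Cz minus the mean of its ring of eight.

    ``eeg`` is (n_channels, n_samples); ``channel_names`` gives the row
    order (case-insensitive). FP1, if present, is ignored.
    """
    names = [str(c).upper() for c in channel_names]
    idx = {}
    for ch in (LAPLACIAN_CENTER,) + LAPLACIAN_RING:
        try:
            idx[ch] = names.index(ch.upper())
        except ValueError:
            raise ValueError(f"required channel {ch!r} missing from recording") from None
    eeg = np.asarray(eeg, dtype=float)
    ring = np.array([idx[ch] for ch in LAPLACIAN_RING])
    return eeg[idx[LAPLACIAN_CENTER]] - eeg[ring].mean(axis=0)


def make_surrogate(eeg: np.ndarray, channel_names, fs: float) -> SurrogatePair:
    """Spatial filter then both temporal filters; the full preprocessing step."""
    surrogate = laplacian_surrogate(eeg, channel_names)
    return SurrogatePair(
        temporal_path=bandpass_mrcp(surrogate, fs),
        spectral_path=highpass_spectral(surrogate, fs),
        fs=fs,
    )


def butterworth_bandpass_gain(f: float, lo: float = BANDPASS_LO,
                              hi: float = BANDPASS_HI,
                              order: int = FILTER_ORDER) -> float:
    """Analytic continuous-time Butterworth band-pass magnitude at ``f`` Hz.

    From the order-``order`` low-pass prototype via the standard band-pass
    transform: ``|H(jw)|^2 = 1 / (1 + ((w^2 - w0^2) / (B w))^(2n))`` with
    ``w0^2 = w_lo * w_hi`` and ``B = w_hi - w_lo``. The forward–reverse
    cascade realises this magnitude squared.
    """
    w, wl, wh = (2 * np.pi * np.asarray(v, dtype=float) for v in (f, lo, hi))
    with np.errstate(divide="ignore"):
        ratio = (w * w - wl * wh) / ((wh - wl) * w)
    return float(1.0 / np.sqrt(1.0 + ratio ** (2 * order)))
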