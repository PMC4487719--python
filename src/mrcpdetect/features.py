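"""Temporal and spectral feature extraction from surrogate-channel epochs.

Temporal features describe the MRCP morphology on the 0.05–10 Hz path:
latency of maximum negativity, mean amplitude, and slope/intercept of
ordinary-least-squares line fits over the whole epoch and over its final
0.5 s (the steep pre-onset segment). Executed movements yield 6 features;
imagery yields 5 (the intercepts are replaced by the final-0.5 s mean,
whose absolute level is more robust when no movement is performed).

Spectral features are mean Welch power densities of the 0.05 Hz high-pass
path in five canonical bands: delta (0–4), theta/mu (4–8), alpha (8–13),
beta (13–30) and gamma (30–100 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .epochs import Epoch

LAST_SEGMENT_S = 0.5


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.lo < self.hi):
            raise ValueError(f"band {self.name}: need 0 <= lo < hi, got "
                             f"({self.lo}, {self.hi})")


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 100.0),
)


@dataclass
class FeatureVector:
    values: np.ndarray
    names: tuple[str, ...]
    feature_type: str           # "temporal" | "spectral"
    mode: str | None = None     # "executed" | "imagery" (temporal only)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.names):
            raise ValueError("values and names must align")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature value")


def _ols_line(t: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(t, x, 1)
    return float(slope), float(intercept)


def temporal_features(epoch: Epoch, mode: str = "executed",
                      regression_until: str = "epoch_end") -> FeatureVector:
    """MRCP morphology features from a temporal-path epoch.

    ``regression_until`` selects the endpoint of the full-epoch regression:
    ``"epoch_end"`` (the detection point, i.e. movement onset) or
    ``"max_negativity"`` (up to and including the minimum sample).
    Time axes are in seconds from epoch start; the latency of maximum
    negativity breaks ties toward the earliest sample.
    """
    if epoch.path != "temporal":
        raise ValueError("temporal features require a temporal-path epoch")
    if mode not in ("executed", "imagery"):
        raise ValueError(f"unknown mode {mode!r}")
    x = np.asarray(epoch.samples, dtype=float)
    t = np.arange(len(x)) / epoch.fs

    i_min = int(np.argmin(x))
    t_min = float(t[i_min])
    mean_all = float(x.mean())
    if regression_until == "epoch_end":
        sl_full, ic_full = _ols_line(t, x)
    elif regression_until == "max_negativity":
        if i_min < 1:
            sl_full, ic_full = 0.0, float(x[0])
        else:
            sl_full, ic_full = _ols_line(t[:i_min + 1], x[:i_min + 1])
    else:
        raise ValueError(f"unknown regression endpoint {regression_until!r}")

    n_last = int(round(LAST_SEGMENT_S * epoch.fs))
    sl_last, ic_last = _ols_line(t[-n_last:], x[-n_last:])

    if mode == "executed":
        return FeatureVector(
            [t_min, mean_all, sl_full, ic_full, sl_last, ic_last],
            ("t_max_negativity", "mean_amplitude", "slope_full",
             "intercept_full", "slope_last", "intercept_last"),
            "temporal", mode)
    mean_last = float(x[-n_last:].mean())
    return FeatureVector(
        [t_min, mean_all, sl_full, sl_last, mean_last],
        ("t_max_negativity", "mean_amplitude", "slope_full",
         "slope_last", "mean_last"),
        "temporal", mode)


def welch_psd(x: np.ndarray, fs: float, seg_len: int | None = None,
              overlap_frac: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch power spectral density (µV²/Hz), Hamming window.

    Default segment length is ``fs`` samples (1 s, hence 1 Hz resolution;
    three segments across a 2 s epoch at 50% overlap). Segments are not
    detrended: the sub-delta content carries the MRCP and must survive.
    """
    x = np.asarray(x, dtype=float)
    if seg_len is None:
        seg_len = int(round(fs))
    if seg_len > len(x):
        raise ValueError(f"segment length {seg_len} exceeds epoch length {len(x)}")
    freqs, psd = signal.welch(
        x, fs=fs, window="hamming", nperseg=seg_len,
        noverlap=int(round(seg_len * overlap_frac)),
        detrend=False, scaling="density")
    return freqs, psd


def band_power(frequencies: np.ndarray, psd: np.ndarray, band: BandDefinition,
               include_upper: bool = False) -> float:
    """Mean PSD over the band's bins, half-open ``[lo, hi)`` by default.

    ``include_upper`` closes the interval at ``hi`` — used for the final
    (gamma) band so its 100 Hz edge is kept.
    """
    frequencies = np.asarray(frequencies)
    mask = (frequencies >= band.lo) & (
        (frequencies <= band.hi) if include_upper else (frequencies < band.hi))
    if not mask.any():
        raise ValueError(
            f"no PSD bins inside band {band.name} ({band.lo}-{band.hi} Hz); "
            "frequency resolution too coarse")
    return float(np.mean(np.asarray(psd)[mask]))


def spectral_features(epoch: Epoch, bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
                      seg_len: int | None = None,
                      overlap_frac: float = 0.5) -> FeatureVector:
    """Mean band powers of a spectral-path epoch over the five default bands."""
    if epoch.path != "spectral":
        raise ValueError("spectral features require a spectral-path epoch")
    freqs, psd = welch_psd(epoch.samples, epoch.fs, seg_len, overlap_frac)
    values = [band_power(freqs, psd, b, include_upper=(i == len(bands) - 1))
              for i, b in enumerate(bands)]
    return FeatureVector(values, tuple(b.name for b in bands), "spectral")


def feature_matrix(epochs: list[Epoch], feature_type: str,
                   mode: str = "executed",
                   regression_until: str = "epoch_end") -> tuple[np.ndarray, np.ndarray]:
    """Stack per-epoch features into (X, y); y is 1 for movement epochs."""
    if feature_type == "temporal":
        fvs = [temporal_features(e, mode, regression_until) for e in epochs]
    elif feature_type == "spectral":
        fvs = [spectral_features(e) for e in epochs]
    else:
        raise ValueError(f"unknown feature type {feature_type!r}")
    X = np.vstack([fv.values for fv in fvs])
    y = np.array([1 if e.label == "movement" else 0 for e in epochs])
    return X, y
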