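"""Readers/writers for recordings, epochs, features and study reports; config.

A recording on disk is either

* *delimited*: a directory with ``eeg.csv`` (header row = channel names, one
  column per channel, time implicit from the sampling rate), ``force.csv``,
  ``events.csv`` (``cue_time_s, task, true_onset_s``) and ``meta.json``
  (rates, group); or
* *EDF*: ``<name>.edf`` holding the EEG channels plus the same
  ``events.csv``/``force.csv`` sidecars. EDF is written by a minimal
  built-in writer (16-bit samples, 1 s data records) and read back through
  MNE.

All times are seconds on the recording clock; sample indices are 0-based
and windows half-open.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import struct
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .features import DEFAULT_BANDS, BandDefinition
from .synthdata import CHANNELS, GROUPS, Recording, SimulationConfig

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# study configuration

@dataclasses.dataclass
class StudyConfig:
    """Flat configuration of the whole pipeline; defaults are the study's values."""

    # simulation (see SimulationConfig for semantics)
    n_trials_per_task: int = 50
    tasks: tuple[str, ...] = ("f60", "s20")
    fs_eeg: float = 500.0
    fs_force: float = 2000.0
    mrcp_peak_amplitude: float = -10.0
    mrcp_rise_start: float = 2.0
    mrcp_recovery: float = 1.0
    background_pink_sd: float = 2.0
    alpha_amplitude: float = 1.0
    alpha_freq: float = 10.0
    channel_gains: dict = dataclasses.field(
        default_factory=lambda: SimulationConfig().channel_gains)
    inter_trial_interval: float = 12.0
    force_noise_sd: float = 0.001
    onset_jitter_max: float = 0.3
    line_noise_amplitude: float = 0.0
    line_noise_freq: float = 50.0
    # preprocessing
    bandpass_lo: float = 0.05
    bandpass_hi: float = 10.0
    highpass_cutoff: float = 0.05
    filter_order: int = 2
    # epochs
    epoch_duration_s: float = 2.0
    noise_offset_s: float = 5.0
    onset_window_s: float = 0.2
    baseline_margin_sd: float = 0.0
    imagery_force_threshold: float = 0.05
    # features
    welch_seg_len: int = 500
    welch_overlap: float = 0.5
    band_edges: tuple = tuple((b.name, b.lo, b.hi) for b in DEFAULT_BANDS)
    temporal_mode: str = "auto"          # auto | executed | imagery
    regression_until: str = "epoch_end"  # epoch_end | max_negativity
    # detection / evaluation
    threshold_step: float = 0.01
    n_folds: int = 5
    template_onset_jitter_sd: float = 0.0
    # bookkeeping
    seed: int = 0
    out_dir: str = "results"

    def validate(self) -> None:
        self.simulation_config().validate()
        for name, lo, hi in self.band_edges:
            BandDefinition(name, float(lo), float(hi))
        if self.temporal_mode not in ("auto", "executed", "imagery"):
            raise ValueError(f"invalid temporal_mode {self.temporal_mode!r}")
        if self.regression_until not in ("epoch_end", "max_negativity"):
            raise ValueError(f"invalid regression_until {self.regression_until!r}")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")

    def simulation_config(self) -> SimulationConfig:
        sim_fields = {f.name for f in dataclasses.fields(SimulationConfig)}
        return SimulationConfig(**{k: v for k, v in dataclasses.asdict(self).items()
                                   if k in sim_fields})

    def bands(self) -> tuple[BandDefinition, ...]:
        return tuple(BandDefinition(n, float(lo), float(hi))
                     for n, lo, hi in self.band_edges)


def load_config(path) -> StudyConfig:
    """Read a flat key-value YAML config; unknown keys are rejected and
    absent keys fall back to the defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must be a flat key-value mapping")
    known = {f.name: f for f in dataclasses.fields(StudyConfig)}
    unknown = set(raw) - set(known)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {}
    for key, value in raw.items():
        if key in ("tasks",):
            value = tuple(value)
        elif key == "band_edges":
            value = tuple((str(n), float(lo), float(hi)) for n, lo, hi in value)
        kwargs[key] = value
    cfg = StudyConfig(**kwargs)
    cfg.validate()
    return cfg


def save_config(cfg: StudyConfig, path) -> None:
    data = dataclasses.asdict(cfg)
    data["tasks"] = list(data["tasks"])
    data["band_edges"] = [list(b) for b in data["band_edges"]]
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


# ---------------------------------------------------------------------------
# delimited recording format

def _write_events(rec: Recording, path: Path) -> None:
    pd.DataFrame({
        "cue_time_s": rec.cue_times,
        "task": rec.task_labels,
        "true_onset_s": (rec.true_onsets if rec.true_onsets is not None
                         else [np.nan] * len(rec.cue_times)),
    }).to_csv(path, index=False)


def write_recording_delimited(rec: Recording, out_dir) -> Path:
    """Write eeg.csv / force.csv / events.csv / meta.json into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rec.eeg.T, columns=list(rec.channels)).to_csv(
        out / "eeg.csv", index=False, float_format="%.6f")
    pd.DataFrame({"force_mvc": rec.force}).to_csv(
        out / "force.csv", index=False, float_format="%.6f")
    _write_events(rec, out / "events.csv")
    (out / "meta.json").write_text(json.dumps({
        "fs_eeg": rec.fs_eeg, "fs_force": rec.fs_force,
        "group": rec.group, "subject_id": rec.subject_id}, indent=1))
    return out


def _map_channels(names: list[str]) -> dict[str, int]:
    lower = {str(n).strip().lower(): i for i, n in enumerate(names)}
    idx = {}
    for ch in CHANNELS:
        if ch.lower() not in lower:
            raise ValueError(f"required channel {ch!r} missing from file")
        idx[ch] = lower[ch.lower()]
    extras = set(lower) - {c.lower() for c in CHANNELS}
    if extras:
        logger.info("ignoring extra channels: %s", sorted(extras))
    return idx


def _read_sidecars(folder: Path, fs_eeg, fs_force, group):
    events = pd.read_csv(folder / "events.csv")
    force = pd.read_csv(folder / "force.csv")["force_mvc"].to_numpy(float)
    meta_path = folder / "meta.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    true_onsets = events["true_onset_s"].to_numpy(float)
    if np.isnan(true_onsets).all():
        true_onsets = None
    return {
        "force": force,
        "fs_eeg": float(meta.get("fs_eeg", fs_eeg)),
        "fs_force": float(meta.get("fs_force", fs_force)),
        "group": meta.get("group", group),
        "subject_id": meta.get("subject_id", folder.stem),
        "cue_times": events["cue_time_s"].to_numpy(float),
        "task_labels": [str(t) for t in events["task"]],
        "true_onsets": true_onsets,
    }


def read_recording(path, fmt: str = "delimited", fs_eeg: float = 500.0,
                   fs_force: float = 2000.0, group: str = "real") -> Recording:
    """Load a recording (``delimited`` directory or ``edf`` file + sidecars).

    Channels are mapped by name, case-insensitively; extra channels are
    ignored with a log line. For delimited data the rates come from
    meta.json when present, else from the arguments; EDF carries its own
    rate. Events and force always come from the sidecar files.
    """
    path = Path(path)
    if fmt == "delimited":
        eeg_df = pd.read_csv(path / "eeg.csv")
        idx = _map_channels(list(eeg_df.columns))
        side = _read_sidecars(path, fs_eeg, fs_force, group)
        eeg = np.vstack([eeg_df.iloc[:, idx[ch]].to_numpy(float) for ch in CHANNELS])
    elif fmt == "edf":
        import mne
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        idx = _map_channels(raw.ch_names)
        side = _read_sidecars(path.parent, fs_eeg, fs_force, group)
        side["fs_eeg"] = float(raw.info["sfreq"])
        data = raw.get_data() * 1e6  # MNE returns volts; the pipeline uses µV
        eeg = np.vstack([data[idx[ch]] for ch in CHANNELS])
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if side["group"] not in GROUPS:
        raise ValueError(f"unknown group {side['group']!r}")
    return Recording(eeg=eeg, channels=CHANNELS, **side)


# ---------------------------------------------------------------------------
# minimal EDF writer (16-bit samples, 1 s records)

def write_recording_edf(rec: Recording, path) -> Path:
    """Serialize the EEG channels to an EDF file plus CSV sidecars.

    Values are stored as 16-bit integers against per-channel physical
    min/max, the format's native precision. The recording is zero-padded to
    a whole number of 1 s data records. Force and events go to
    ``force.csv``/``events.csv`` next to the file.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fs = int(round(rec.fs_eeg))
    if abs(fs - rec.fs_eeg) > 1e-9:
        raise ValueError("EDF writer requires an integer EEG sampling rate")
    n_ch = len(rec.channels)
    n = rec.eeg.shape[1]
    n_records = int(np.ceil(n / fs))
    data = np.zeros((n_ch, n_records * fs))
    data[:, :n] = rec.eeg

    phys_min = np.floor(data.min(axis=1)) - 1.0
    phys_max = np.ceil(data.max(axis=1)) + 1.0
    dig_min, dig_max = -32768, 32767

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    header = b"".join([
        pad("0", 8), pad("X X X X", 80), pad("X X X", 80),
        pad("01.01.00", 8), pad("00.00.00", 8),
        pad(str(256 * (n_ch + 1)), 8), pad("", 44),
        pad(str(n_records), 8), pad("1", 8), pad(str(n_ch), 4),
    ])
    fields = [
        ("".join(pad(ch, 16).decode() for ch in rec.channels), None),
        ("".join(pad("EEG electrode", 80).decode() for _ in rec.channels), None),
        ("".join(pad("uV", 8).decode() for _ in rec.channels), None),
        ("".join(pad(f"{v:g}", 8).decode() for v in phys_min), None),
        ("".join(pad(f"{v:g}", 8).decode() for v in phys_max), None),
        ("".join(pad(str(dig_min), 8).decode() for _ in rec.channels), None),
        ("".join(pad(str(dig_max), 8).decode() for _ in rec.channels), None),
        ("".join(pad("", 80).decode() for _ in rec.channels), None),
        ("".join(pad(str(fs), 8).decode() for _ in rec.channels), None),
        ("".join(pad("", 32).decode() for _ in rec.channels), None),
    ]
    header += "".join(f[0] for f in fields).encode("ascii")

    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip(np.round((data - phys_min[:, None]) * scale[:, None])
                      + dig_min, dig_min, dig_max).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            for c in range(n_ch):
                fh.write(digital[c, r * fs:(r + 1) * fs].tobytes())
    pd.DataFrame({"force_mvc": rec.force}).to_csv(
        path.parent / "force.csv", index=False, float_format="%.6f")
    _write_events(rec, path.parent / "events.csv")
    (path.parent / "meta.json").write_text(json.dumps({
        "fs_eeg": rec.fs_eeg, "fs_force": rec.fs_force,
        "group": rec.group, "subject_id": rec.subject_id}, indent=1))
    return path


# ---------------------------------------------------------------------------
# epochs / features / reports

def write_epochs(epochs, path) -> None:
    """One row per epoch: subject, task, label, path, t0, then the samples."""
    rows = []
    for e in epochs:
        rows.append({"subject": e.subject_id, "task": e.task, "label": e.label,
                     "path": e.path, "t0": e.t0, "fs": e.fs,
                     **{f"s{i}": v for i, v in enumerate(e.samples)}})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")


def read_epochs(path):
    from .epochs import Epoch
    df = pd.read_csv(path)
    sample_cols = [c for c in df.columns if c.startswith("s") and c[1:].isdigit()]
    sample_cols.sort(key=lambda c: int(c[1:]))
    return [Epoch(row[sample_cols].to_numpy(float), row["label"], row["task"],
                  float(row["t0"]), row["path"], float(row["fs"]), row["subject"])
            for _, row in df.iterrows()]


def write_feature_table(epochs, feature_vectors, path) -> None:
    rows = []
    for e, fv in zip(epochs, feature_vectors):
        rows.append({"subject": e.subject_id, "task": e.task, "label": e.label,
                     "feature_type": fv.feature_type,
                     **dict(zip(fv.names, fv.values))})
    pd.DataFrame(rows).to_csv(path, index=False)


def _round_floats(obj, ndigits=6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def write_report(report, path) -> None:
    """Machine-readable study report (JSON, deterministic layout; floats
    rounded to 6 decimals)."""
    Path(path).write_text(json.dumps(_round_floats({
        "config": report.config,
        "aggregate": report.aggregate,
        "friedman": report.friedman,
        "per_subject": report.per_subject,
    }), indent=1, sort_keys=True))


def format_summary(report) -> str:
    """Plain-text aggregate table: mean ± SE per group, method and metric."""
    lines = []
    for group, metrics in sorted(report.aggregate.items()):
        lines.append(f"{group} movements")
        lines.append(f"  {'metric':<12}" + "".join(f"{m:>16}" for m in METHODS_ORDER))
        for metric in ("error", "sensitivity", "specificity"):
            cells = []
            for m in METHODS_ORDER:
                v = metrics[metric][m]
                cells.append(f"{100 * v['mean']:6.1f} ± {100 * v['se']:4.1f}%")
            lines.append(f"  {metric:<12}" + "".join(f"{c:>16}" for c in cells))
        for name, fr in sorted(report.friedman.get(group, {}).items()):
            extra = f" (best: {fr['best']})" if "best" in fr else ""
            lines.append(f"  Friedman {name}: chi2 = {fr['statistic']:.2f}, "
                         f"p = {fr['p']:.4f}{extra}")
    return "\n".join(lines)


METHODS_ORDER = ("lda_temporal", "lda_spectral", "template")
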