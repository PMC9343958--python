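"""Artifact screening, zero-phase bandpass filtering, fractional-stride
windowing, per-window normalization, and train/test splitting.

The windowing rule places window ``k`` at start sample
``floor(k * stride_s * fs)`` — the accumulated-fractional-stride rule.  At
512 Hz with a 0.1 s stride this advances by 51.2 samples per step, so a
16-s recording yields exactly 140 windows of length 1,028 and 68
recordings yield 9,520.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Literal

import numpy as np
from scipy import signal as sps

from .synth import Recording, RecordingSet

__all__ = [
    "PreprocessConfig",
    "WindowMatrix",
    "DataSplit",
    "ScreenReport",
    "screen_artifacts",
    "bandpass",
    "window",
    "window_starts",
    "expected_window_count",
    "normalize",
    "split",
    "preprocess_recordings",
]


class PreprocessError(ValueError):
    """Raised for invalid preprocessing inputs or configuration."""


@dataclass(frozen=True)
class PreprocessConfig:
    band_low: float = 8.0
    band_high: float = 40.0
    filter_order: int = 4
    window_len: int = 1028
    stride_s: float = 0.1
    normalization: Literal["zscore", "none"] = "zscore"
    amplitude_threshold: float = 100.0  # microvolts
    flatline_run: int = 512  # samples (1 s at 512 Hz)

    def __post_init__(self) -> None:
        if not (0 < self.band_low < self.band_high):
            raise PreprocessError(
                f"require 0 < band_low < band_high, got ({self.band_low}, {self.band_high})"
            )
        if self.stride_s <= 0:
            raise PreprocessError(f"stride_s must be positive, got {self.stride_s}")
        if self.window_len < 1:
            raise PreprocessError(f"window_len must be >= 1, got {self.window_len}")


@dataclass(frozen=True)
class ScreenReport:
    accepted: bool
    violations: tuple[str, ...]


@dataclass(frozen=True)
class WindowMatrix:
    """Segmented data: n x window_len x n_channels, with per-window labels
    and the source recording id (group) of every window."""

    windows: np.ndarray
    labels: np.ndarray
    groups: np.ndarray
    class_order: tuple[str, ...]

    def __post_init__(self) -> None:
        windows = np.asarray(self.windows)
        object.__setattr__(self, "windows", windows)
        object.__setattr__(self, "labels", np.asarray(self.labels))
        object.__setattr__(self, "groups", np.asarray(self.groups))
        if windows.ndim != 3:
            raise PreprocessError("windows must be n x window_len x n_channels")
        n = windows.shape[0]
        if len(self.labels) != n or len(self.groups) != n:
            raise PreprocessError("labels and groups must align with windows")

    def __len__(self) -> int:
        return self.windows.shape[0]

    def subset(self, idx: np.ndarray) -> "WindowMatrix":
        return WindowMatrix(
            windows=self.windows[idx],
            labels=self.labels[idx],
            groups=self.groups[idx],
            class_order=self.class_order,
        )


@dataclass(frozen=True)
class DataSplit:
    train: WindowMatrix
    test: WindowMatrix
    mode: Literal["segment", "group"]
    fraction: float
    seed: int
    train_idx: np.ndarray = field(repr=False, default=None)
    test_idx: np.ndarray = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

def _longest_constant_run(x: np.ndarray) -> tuple[int, int]:
    """Length and start of the longest run of consecutive equal samples."""
    if x.size == 0:
        return 0, 0
    change = np.flatnonzero(np.diff(x) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [x.size]))
    runs = ends - starts
    best = int(np.argmax(runs))
    return int(runs[best]), int(starts[best])


def screen_artifacts(recording: Recording, config: PreprocessConfig) -> ScreenReport:
    """Accept/reject a recording on amplitude and flatline rules.

    Side-effect free and idempotent: always returns a decision, never
    modifies the recording.
    """
    violations: list[str] = []
    over = np.abs(recording.samples) > config.amplitude_threshold
    if over.any():
        ch, pos = np.unravel_index(int(np.argmax(over)), over.shape)
        violations.append(
            f"amplitude: |sample| > {config.amplitude_threshold} uV at "
            f"channel {recording.channel_labels[ch]}, sample {pos}"
        )
    for ch in range(recording.n_channels):
        run, start = _longest_constant_run(recording.samples[ch])
        if run >= config.flatline_run:
            violations.append(
                f"flatline: constant run of {run} samples (>= {config.flatline_run}) "
                f"at channel {recording.channel_labels[ch]}, sample {start}"
            )
    return ScreenReport(accepted=not violations, violations=tuple(violations))


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def _design_bandpass(config: PreprocessConfig, fs: float):
    nyq = fs / 2.0
    if not (0 < config.band_low < config.band_high < nyq):
        raise PreprocessError(
            f"band ({config.band_low}, {config.band_high}) Hz outside (0, {nyq}) Hz"
        )
    return sps.butter(
        config.filter_order,
        [config.band_low, config.band_high],
        btype="bandpass",
        fs=fs,
        output="sos",
    )


def bandpass(recording: Recording, config: PreprocessConfig) -> Recording:
    """Zero-phase Butterworth bandpass, each channel filtered independently."""
    sos = _design_bandpass(config, recording.fs)
    filtered = sps.sosfiltfilt(sos, recording.samples, axis=1)
    return replace(recording, samples=filtered)


def bandpass_response_db(config: PreprocessConfig, fs: float, freq_hz: float) -> float:
    """Two-pass (forward-backward) magnitude response of the designed filter
    at one frequency, in dB.  Independent oracle for attenuation tests."""
    sos = _design_bandpass(config, fs)
    _, h = sps.sosfreqz(sos, worN=[freq_hz], fs=fs)
    mag = np.abs(h[0]) ** 2  # filtfilt applies the filter twice
    return float(20.0 * np.log10(mag)) if mag > 0 else -np.inf


# ---------------------------------------------------------------------------
# windowing
# ---------------------------------------------------------------------------

def _stride_fraction(stride_s: float, fs: float) -> Fraction:
    # exact rational stride in samples; str() round-trips the intended
    # decimal (0.1 -> 1/10) instead of the float's binary expansion
    return Fraction(str(stride_s)) * Fraction(str(fs))


def window_starts(n_samples: int, window_len: int, stride_s: float, fs: float) -> list[int]:
    """Start positions floor(k * stride_s * fs) while start + window_len fits."""
    step = _stride_fraction(stride_s, fs)
    if step <= 0:
        raise PreprocessError("stride must be positive")
    starts = []
    k = 0
    while True:
        start = int(k * step)  # Fraction -> floor for nonnegative values
        if start + window_len > n_samples:
            break
        starts.append(start)
        k += 1
    return starts


def expected_window_count(n_samples: int, window_len: int, stride_s: float, fs: float) -> int:
    """Closed form for the floor-of-accumulated-stride rule.

    floor(k * step) + window_len <= n holds iff k < (n - window_len + 1) / step,
    so the count is ceil((n - window_len + 1) / step), in exact rational
    arithmetic.  Zero when the recording is shorter than a window.
    """
    if n_samples < window_len:
        return 0
    step = _stride_fraction(stride_s, fs)
    val = Fraction(n_samples - window_len + 1) / step
    return int(-(-val.numerator // val.denominator))


def window(recordings: RecordingSet | Iterable[Recording], config: PreprocessConfig) -> WindowMatrix:
    """Segment every recording into overlapping windows.

    Both channels of a recording travel in the same window (shape
    window_len x n_channels); the window count is per recording, not per
    channel.
    """
    recs = list(recordings)
    if not recs:
        raise PreprocessError("no recordings to window")
    chunks, labels, groups = [], [], []
    for rec in recs:
        if rec.n_samples < config.window_len:
            raise PreprocessError(
                f"recording {rec.recording_id} has {rec.n_samples} samples, "
                f"shorter than window_len {config.window_len}"
            )
        starts = window_starts(rec.n_samples, config.window_len, config.stride_s, rec.fs)
        data = rec.samples.T  # time x channels
        for s in starts:
            chunks.append(data[s : s + config.window_len])
        labels.extend([rec.stimulus] * len(starts))
        groups.extend([rec.recording_id] * len(starts))
    class_order = tuple(dict.fromkeys(r.stimulus for r in recs))
    return WindowMatrix(
        windows=np.stack(chunks).astype(np.float32),
        labels=np.asarray(labels),
        groups=np.asarray(groups),
        class_order=class_order,
    )


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize(wm: WindowMatrix, method: str = "zscore") -> WindowMatrix:
    """Per-window per-channel z-score; constant windows map to zeros."""
    if method == "none":
        return wm
    if method != "zscore":
        raise PreprocessError(f"unknown normalization method {method!r}")
    mean = wm.windows.mean(axis=1, keepdims=True)
    sd = wm.windows.std(axis=1, keepdims=True)
    safe_sd = np.where(sd > 0, sd, 1.0)
    out = (wm.windows - mean) / safe_sd
    out = np.where(sd > 0, out, 0.0)
    return replace(wm, windows=out.astype(np.float32))


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def _stratified_pick(keys: np.ndarray, labels: np.ndarray, fraction: float,
                     rng: np.random.Generator) -> set:
    """Pick round(n_c * fraction) keys per class, shuffled within class."""
    chosen = set()
    for cls in dict.fromkeys(labels.tolist()):
        cls_keys = keys[labels == cls]
        n_train = int(round(len(cls_keys) * fraction))
        perm = rng.permutation(len(cls_keys))
        chosen.update(cls_keys[perm[:n_train]].tolist())
    return chosen


def split(wm: WindowMatrix, fraction: float = 0.7,
          mode: Literal["segment", "group"] = "group", seed: int = 0) -> DataSplit:
    """Stratified train/test split of windows or of whole recordings.

    ``group`` mode keeps all windows of a recording on the same side, which
    avoids the train/test leakage created by heavily overlapping windows;
    ``segment`` mode splits windows directly.
    """
    if not (0 < fraction < 1):
        raise PreprocessError(f"fraction must be in (0, 1), got {fraction}")
    for cls in wm.class_order:
        if not np.any(wm.labels == cls):
            raise PreprocessError(f"class {cls!r} absent from input")
    rng = np.random.default_rng(seed)
    if mode == "segment":
        idx = np.arange(len(wm))
        train_set = _stratified_pick(idx, wm.labels, fraction, rng)
        train_mask = np.isin(idx, list(train_set))
    elif mode == "group":
        group_ids, first = np.unique(wm.groups, return_index=True)
        group_labels = wm.labels[first]
        train_groups = _stratified_pick(group_ids, group_labels, fraction, rng)
        train_mask = np.isin(wm.groups, list(train_groups))
    else:
        raise PreprocessError(f"unknown split mode {mode!r}")
    train_idx = np.flatnonzero(train_mask)
    test_idx = np.flatnonzero(~train_mask)
    return DataSplit(
        train=wm.subset(train_idx),
        test=wm.subset(test_idx),
        mode=mode,
        fraction=fraction,
        seed=seed,
        train_idx=train_idx,
        test_idx=test_idx,
    )


# ---------------------------------------------------------------------------
# convenience pipeline stage
# ---------------------------------------------------------------------------

def preprocess_recordings(
    rs: RecordingSet, config: PreprocessConfig
) -> tuple[WindowMatrix, list[tuple[str, ScreenReport]]]:
    """screen -> filter -> window -> normalize; returns the matrix plus the
    screening reports of rejected recordings."""
    kept, rejected = [], []
    for rec in rs:
        report = screen_artifacts(rec, config)
        if report.accepted:
            kept.append(bandpass(rec, config))
        else:
            rejected.append((rec.recording_id, report))
    if not kept:
        raise PreprocessError("all recordings rejected by artifact screening")
    wm = window(kept, config)
    wm = normalize(wm, config.normalization)
    return wm, rejected
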