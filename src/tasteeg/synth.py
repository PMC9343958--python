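"""Synthetic 2-channel EEG generator with controllable class separability.

Each trial is modelled as a 1/f^alpha background plus class-specific
band-limited oscillations (8-40 Hz) modulated by an onset-rise/decay
envelope, plus broadband white noise.  Class identity is carried purely
by the band-power profile, scaled by ``effect_size`` (0 = classes are
statistically identical).  Transient high-amplitude artifacts can be
injected separately to exercise artifact screening.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SynthConfig",
    "Recording",
    "RecordingSet",
    "generate_recording",
    "generate_dataset",
    "inject_artifacts",
    "write_recording_set",
    "read_recording_set",
    "DEFAULT_CLASSES",
    "DEFAULT_PROFILES",
]

DEFAULT_CLASSES = ("water", "sucrose", "aspartame", "sucralose")

# One narrow band per class, spaced inside the 8-40 Hz analysis band so the
# class signal survives the default bandpass. (center Hz, bandwidth Hz,
# relative power) triples; a class may own several bands.
DEFAULT_PROFILES = {
    "water": ((10.0, 2.0, 1.0),),
    "sucrose": ((16.0, 2.0, 1.0),),
    "aspartame": ((24.0, 2.0, 1.0),),
    "sucralose": ((32.0, 2.0, 1.0),),
}


class SynthError(ValueError):
    """Raised for invalid synthetic-generator inputs."""


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic EEG dataset generator."""

    n_subjects: int = 11
    n_sessions_per_subject: int = 3
    classes: tuple[str, ...] = DEFAULT_CLASSES
    fs: float = 512.0
    duration_s: float = 16.0
    n_channels: int = 2
    channel_labels: tuple[str, ...] = ("C3", "C4")
    class_profiles: dict[str, tuple[tuple[float, float, float], ...]] = field(
        default_factory=lambda: dict(DEFAULT_PROFILES)
    )
    effect_size: float = 1.0
    background_exponent: float = 1.0
    background_scale: float = 10.0
    envelope: tuple[float, float] = (1.0, 8.0)  # (rise s, decay time-constant s)
    artifact_rate: float = 0.0
    artifact_amplitude: float = 500.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise SynthError(f"fs must be positive, got {self.fs}")
        if self.duration_s <= 0:
            raise SynthError(f"duration_s must be positive, got {self.duration_s}")
        if self.effect_size < 0:
            raise SynthError(f"effect_size must be >= 0, got {self.effect_size}")
        if len(set(self.classes)) != len(self.classes):
            raise SynthError("class labels must be distinct")
        if self.n_channels != len(self.channel_labels):
            raise SynthError(
                f"n_channels={self.n_channels} does not match "
                f"{len(self.channel_labels)} channel labels"
            )
        for cls in self.classes:
            if cls not in self.class_profiles:
                raise SynthError(f"no spectral profile for class {cls!r}")
            for center, bw, power in self.class_profiles[cls]:
                if not (8.0 <= center <= 40.0):
                    raise SynthError(
                        f"profile center {center} Hz for {cls!r} outside [8, 40]"
                    )
                if bw <= 0 or power < 0:
                    raise SynthError(f"invalid profile ({center}, {bw}, {power})")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration_s))


@dataclass(frozen=True)
class Recording:
    """One labeled EEG trial: channels x time, in microvolts."""

    samples: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    stimulus: str
    subject_id: str
    session_id: str
    recording_id: str

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 2:
            raise SynthError("samples must be a 2-D channels x time array")
        if samples.shape[0] != len(self.channel_labels):
            raise SynthError(
                f"channel count {samples.shape[0]} does not match labels "
                f"{self.channel_labels}"
            )
        if not np.all(np.isfinite(samples)):
            raise SynthError(f"recording {self.recording_id} contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]


@dataclass(frozen=True)
class RecordingSet:
    """A collection of recordings plus a tidy manifest table."""

    recordings: tuple[Recording, ...]
    manifest: pd.DataFrame

    def __post_init__(self) -> None:
        ids = [r.recording_id for r in self.recordings]
        if len(set(ids)) != len(ids):
            raise SynthError("recording_ids must be unique")
        if len(self.manifest) != len(self.recordings):
            raise SynthError("manifest rows must correspond 1:1 to recordings")
        if list(self.manifest["recording_id"]) != ids:
            raise SynthError("manifest order must match recordings")

    def __len__(self) -> int:
        return len(self.recordings)

    def __iter__(self):
        return iter(self.recordings)

    @property
    def classes(self) -> tuple[str, ...]:
        seen: list[str] = []
        for r in self.recordings:
            if r.stimulus not in seen:
                seen.append(r.stimulus)
        return tuple(seen)


def _recording_seed(base_seed: int, subject_id: str, session_id: str, stimulus: str) -> int:
    """Stable per-recording seed from (base seed, subject, session, class).

    SHA-256 keyed derivation so any single recording is reproducible in
    isolation, independent of generation order.
    """
    key = f"{base_seed}|{subject_id}|{session_id}|{stimulus}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:8], "little")


def _pink_noise(rng: np.random.Generator, n: int, fs: float, exponent: float) -> np.ndarray:
    """1/f^alpha noise via spectral shaping of white Gaussian noise."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nonzero = freqs > 0
    shaping[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC drift
    shaped = np.fft.irfft(spectrum * shaping, n=n)
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


def _band_noise(
    rng: np.random.Generator, n: int, fs: float, center: float, bandwidth: float
) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise via an FFT brickwall mask."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= center - bandwidth / 2.0) & (freqs <= center + bandwidth / 2.0)
    band = np.fft.irfft(spectrum * mask, n=n)
    sd = band.std()
    return band / sd if sd > 0 else band


def onset_envelope(n: int, fs: float, rise_s: float, decay_s: float) -> np.ndarray:
    """Post-onset activity envelope: linear rise then exponential decay."""
    t = np.arange(n) / fs
    env = np.ones(n)
    if rise_s > 0:
        env = np.minimum(t / rise_s, 1.0)
    if decay_s > 0:
        after = t > rise_s
        env[after] *= np.exp(-(t[after] - rise_s) / decay_s)
    return env


def generate_recording(
    config: SynthConfig,
    stimulus: str,
    subject_id: str,
    session_id: str,
    seed: int,
) -> Recording:
    """Generate one deterministic synthetic trial for the given stimulus.

    The same (config, stimulus, ids, seed) always yields bit-identical
    samples.
    """
    if stimulus not in config.classes:
        raise SynthError(
            f"unknown stimulus {stimulus!r}; expected one of {config.classes}"
        )
    rng = np.random.default_rng(seed)
    n = config.n_samples
    rise_s, decay_s = config.envelope
    env = onset_envelope(n, config.fs, rise_s, decay_s)

    samples = np.empty((config.n_channels, n))
    for ch in range(config.n_channels):
        background = config.background_scale * _pink_noise(
            rng, n, config.fs, config.background_exponent
        )
        oscillation = np.zeros(n)
        for center, bandwidth, rel_power in config.class_profiles[stimulus]:
            # oscillation power scales linearly with effect_size; amplitudes
            # stay below screening thresholds for effect sizes up to ~10
            amp = 0.5 * config.background_scale * np.sqrt(config.effect_size * rel_power)
            oscillation += amp * _band_noise(rng, n, config.fs, center, bandwidth)
        noise = config.noise_sd * rng.standard_normal(n)
        samples[ch] = background + env * oscillation + noise

    rec = Recording(
        samples=samples,
        fs=config.fs,
        channel_labels=config.channel_labels,
        stimulus=stimulus,
        subject_id=subject_id,
        session_id=session_id,
        recording_id=f"{subject_id}_{session_id}_{stimulus}",
    )
    if config.artifact_rate > 0:
        rec = inject_artifacts(
            rec,
            rate=config.artifact_rate,
            amplitude=config.artifact_amplitude,
            seed=seed + 1,
        )
    return rec


def generate_dataset(config: SynthConfig) -> RecordingSet:
    """Balanced design: one recording per (subject, session, class).

    Per-recording seeds are derived from ``config.seed`` by keyed hashing,
    so the full dataset and any single trial are independently reproducible.
    """
    recordings: list[Recording] = []
    rows: list[dict] = []
    for si in range(config.n_subjects):
        subject_id = f"S{si + 1:02d}"
        for se in range(config.n_sessions_per_subject):
            session_id = f"sess{se + 1}"
            for stimulus in config.classes:
                seed = _recording_seed(config.seed, subject_id, session_id, stimulus)
                rec = generate_recording(config, stimulus, subject_id, session_id, seed)
                recordings.append(rec)
                rows.append(
                    {
                        "recording_id": rec.recording_id,
                        "subject": subject_id,
                        "session": session_id,
                        "stimulus": stimulus,
                        "path": "",
                    }
                )
    manifest = pd.DataFrame(rows, columns=["recording_id", "subject", "session", "stimulus", "path"])
    return RecordingSet(recordings=tuple(recordings), manifest=manifest)


def inject_artifacts(
    recording: Recording, rate: float, amplitude: float, seed: int
) -> Recording:
    """Add Poisson(rate) transient spikes of the given peak amplitude.

    Returns a new Recording; the input is left unmodified.  Each spike is a
    ~50 ms raised-cosine transient on one randomly chosen channel with a
    random sign.
    """
    if rate < 0:
        raise SynthError(f"artifact rate must be >= 0, got {rate}")
    rng = np.random.default_rng(seed)
    samples = recording.samples.copy()
    n = samples.shape[1]
    n_spikes = rng.poisson(rate)
    width = max(int(round(0.05 * recording.fs)), 3)
    kernel = np.hanning(width)
    for _ in range(n_spikes):
        pos = int(rng.integers(0, max(n - width, 1)))
        ch = int(rng.integers(0, samples.shape[0]))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        samples[ch, pos : pos + width] += sign * amplitude * kernel[: n - pos]
    return replace(recording, samples=samples)


# ---------------------------------------------------------------------------
# on-disk representation: one CSV per recording + a manifest CSV
# ---------------------------------------------------------------------------

def write_recording_set(rs: RecordingSet, out_dir: str | Path) -> Path:
    """Write per-recording CSV time series plus ``manifest.csv``.

    Each recording file has one column per channel (header = channel
    labels), single-precision values; the manifest has columns
    recording_id,subject,session,stimulus,path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec, row in zip(rs.recordings, rs.manifest.to_dict("records")):
        fname = f"{rec.recording_id}.csv"
        df = pd.DataFrame(
            rec.samples.T.astype(np.float32), columns=list(rec.channel_labels)
        )
        df.to_csv(out_dir / fname, index=False)
        row = dict(row)
        row["path"] = fname
        rows.append(row)
    manifest = pd.DataFrame(rows, columns=["recording_id", "subject", "session", "stimulus", "path"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return out_dir / "manifest.csv"


def read_recording_set(manifest_path: str | Path, fs: float = 512.0) -> RecordingSet:
    """Load a RecordingSet from a manifest CSV written by write_recording_set."""
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path, dtype={"recording_id": str, "subject": str, "session": str})
    base = manifest_path.parent
    recordings = []
    for row in manifest.to_dict("records"):
        df = pd.read_csv(base / row["path"])
        recordings.append(
            Recording(
                samples=df.to_numpy().T,
                fs=fs,
                channel_labels=tuple(df.columns),
                stimulus=row["stimulus"],
                subject_id=row["subject"],
                session_id=row["session"],
                recording_id=row["recording_id"],
            )
        )
    return RecordingSet(recordings=tuple(recordings), manifest=manifest)
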