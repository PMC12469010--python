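"""Synthetic two-class EEG cohorts with planted band-specific class effects.

Each subject's channel is a sum of band-limited oscillations (one per EEG band
theta 4-8 Hz, beta 16-32 Hz, gamma 32-64 Hz, with per-subject-and-channel
random frequency and phase), a subject-level multiplicative gain, pink (1/f)
background noise and white sensor noise. Class membership changes the band
amplitudes: by default the normal class is higher in every band, with the
largest normal-vs-ASD gap in beta, then gamma, then theta, and the ASD class
additionally receives a slow random amplitude envelope emulating inconsistent
band-power fluctuation.

The generator is deterministic given ``(seed, subject_index, class_label)``
and emits the same CSV + JSON sidecar formats the I/O layer reads, so a
simulated cohort directory is a drop-in replacement for real exported data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError
from .signal_io import (
    ASD,
    DEFAULT_CHANNELS_15,
    NORMAL,
    CohortManifest,
    ManifestEntry,
    SignalRecord,
    save_manifest,
    write_signal,
)

#: Nominal EEG band edges in Hz used by the generator.
BAND_RANGES = {"theta": (4.0, 8.0), "beta": (16.0, 32.0), "gamma": (32.0, 64.0)}

#: Default (normal, ASD) oscillation amplitudes per band, microvolt-scale.
#: Normal >= ASD everywhere; gap ordering beta > gamma > theta.
DEFAULT_BAND_AMPLITUDES = {
    "theta": (10.0, 9.0),
    "beta": (12.0, 6.0),
    "gamma": (8.0, 5.0),
}

_CLASS_CODE = {NORMAL: 0, ASD: 1}


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition parameters of a simulated cohort.

    Defaults mirror the source cohort's shape: 8 subjects per class, 15
    channels at 256 Hz, 4 s per subject (1024 samples, decomposable to J=6).
    """

    n_subjects_per_class: int = 8
    fs: float = 256.0
    duration_s: float = 4.0
    n_channels: int = 15
    band_amplitudes: dict = field(default_factory=lambda: dict(DEFAULT_BAND_AMPLITUDES))
    subject_gain_sd: float = 0.1
    white_sd: float = 3.0
    pink_scale: float = 3.0
    asd_envelope_strength: float = 0.3
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_subjects_per_class < 1:
            raise ConfigError("need at least one subject per class")
        if self.n_channels < 1:
            raise ConfigError("need at least one channel")
        n = self.fs * self.duration_s
        if abs(n - round(n)) > 1e-9 or n < 64:
            raise ConfigError(
                f"fs * duration_s must be an integer >= 64 (J=6 decomposable), got {n}"
            )
        for band, amps in self.band_amplitudes.items():
            if band not in BAND_RANGES:
                raise ConfigError(f"unknown band {band!r}; expected {sorted(BAND_RANGES)}")
            if len(amps) != 2 or min(amps) < 0:
                raise ConfigError(f"band {band}: need (normal_amp, asd_amp) >= 0")
        for name in ("subject_gain_sd", "white_sd", "pink_scale", "asd_envelope_strength"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration_s))

    def channel_labels(self) -> tuple[str, ...]:
        if self.n_channels <= len(DEFAULT_CHANNELS_15):
            return DEFAULT_CHANNELS_15[: self.n_channels]
        return tuple(f"CH{i + 1:02d}" for i in range(self.n_channels))


def _pink_noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """1/f-amplitude-shaped Gaussian noise, rescaled to standard deviation sd."""
    if sd == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    shape = np.zeros_like(freqs)
    shape[1:] = 1.0 / np.sqrt(freqs[1:])
    spec *= shape
    x = np.fft.irfft(spec, n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def _slow_envelope(rng: np.random.Generator, n: int, fs: float, cutoff_hz: float = 0.5) -> np.ndarray:
    """Zero-mean, unit-sd low-pass random envelope (timescale >= 2 s)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[freqs > cutoff_hz] = 0.0
    env = np.fft.irfft(spec, n)
    env -= env.mean()
    s = env.std()
    return env / s if s > 0 else env


def simulate_subject(spec: CohortSpec, subject_index: int, class_label: str) -> SignalRecord:
    """One subject's record; deterministic given (spec.seed, index, class)."""
    if class_label not in _CLASS_CODE:
        raise ConfigError(f"class_label must be ASD or NORMAL, got {class_label!r}")
    rng = np.random.default_rng(
        [int(spec.seed), _CLASS_CODE[class_label], int(subject_index)]
    )
    n = spec.n_samples
    t = np.arange(n) / spec.fs
    gain = 1.0 + spec.subject_gain_sd * rng.standard_normal()
    amp_col = 1 if class_label == ASD else 0

    # per-subject, per-band slow envelopes (ASD instability); drawn for both
    # classes to keep the stream layout class-independent, applied to ASD only
    envelopes = {
        band: _slow_envelope(rng, n, spec.fs) for band in sorted(spec.band_amplitudes)
    }

    data = np.zeros((n, spec.n_channels))
    for c in range(spec.n_channels):
        x = np.zeros(n)
        for band in sorted(spec.band_amplitudes):
            f_lo, f_hi = BAND_RANGES[band]
            amp = spec.band_amplitudes[band][amp_col]
            freq = rng.uniform(f_lo, f_hi)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            osc = amp * gain * np.sin(2.0 * np.pi * freq * t + phase)
            if class_label == ASD and spec.asd_envelope_strength > 0:
                osc = osc * np.maximum(
                    1.0 + spec.asd_envelope_strength * envelopes[band], 0.05
                )
            x += osc
        x += _pink_noise(rng, n, spec.pink_scale)
        x += spec.white_sd * rng.standard_normal(n)
        data[:, c] = x
    return SignalRecord(
        subject_id=f"{class_label}-{subject_index + 1:02d}",
        class_label=class_label,
        fs=spec.fs,
        channel_labels=spec.channel_labels(),
        data=data,
    )


def simulate_cohort(
    spec: CohortSpec, out_dir: str | Path | None = None
) -> tuple[CohortManifest, list[SignalRecord]]:
    """All records of a two-class cohort; optionally written as a directory.

    With ``out_dir`` set, one CSV + JSON sidecar pair per subject and a
    ``manifest.json`` are written, ready for :func:`~subband_flda.signal_io.load_manifest`.
    """
    records = []
    for label in (NORMAL, ASD):
        for i in range(spec.n_subjects_per_class):
            records.append(simulate_subject(spec, i, label))
    entries = [
        ManifestEntry(
            subject_id=r.subject_id,
            class_label=r.class_label,
            data_path=f"{r.subject_id}.csv",
            sidecar_path=f"{r.subject_id}.json",
        )
        for r in records
    ]
    manifest = CohortManifest(entries=entries)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for r, e in zip(records, entries):
            write_signal(r, out_dir / e.data_path, out_dir / e.sidecar_path)
        save_manifest(manifest, out_dir / "manifest.json")
        manifest.validate(root=out_dir)
    return manifest, records
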