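"""Seeded synthetic EEG generator for the two Bonn-like classes.

The generator emulates the statistical contrast the classifier relies on:

* *ictal-like* records — high-amplitude rhythmic oscillations with a
  fundamental drawn from the 3-5 Hz band (the spike-and-wave range of
  generalized seizures), decaying 2nd/3rd harmonics, slow amplitude
  modulation and a small amount of broadband noise;
* *interictal-like* records — low-amplitude 1/f-shaped coloured noise mixed
  with a weak alpha-band (8-12 Hz) rhythm, as seen in background EEG.

Every record is fully determined by ``(seed, index)`` through an independent
:class:`numpy.random.SeedSequence` substream, so datasets are byte-identical
across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_io import BONN_FS, EEGRecord

#: pseudo-subjects per class, mirroring the five subjects per Bonn group
GROUPS_PER_CLASS = 5


@dataclass
class SynthSpec:
    """Parameters of the synthetic two-class EEG dataset."""

    n_per_class: int = 100
    n_samples: int = 4097
    fs: float = BONN_FS
    ictal_amplitude: float = 800.0        # uV
    interictal_amplitude: float = 200.0   # uV
    ictal_freq_range: tuple[float, float] = (3.0, 5.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.ictal_amplitude < 0 or self.interictal_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.ictal_amplitude <= self.interictal_amplitude and (
            self.ictal_amplitude or self.interictal_amplitude
        ):
            raise ValueError(
                "ictal_amplitude must exceed interictal_amplitude "
                "(class separability by construction)"
            )
        lo, hi = self.ictal_freq_range
        if not (0 < lo < hi < self.fs / 2):
            raise ValueError("need 0 < ictal_freq low < high < fs/2")


def _rng(spec: SynthSpec, kind: str, index: int) -> np.random.Generator:
    # one independent substream per (seed, class, index)
    key = {"ictal": 0, "interictal": 1}[kind]
    return np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(key, index))
    )


def _group_id(kind: str, index: int, n_per_class: int) -> str:
    block = max(1, int(np.ceil(n_per_class / GROUPS_PER_CLASS)))
    return f"{kind[:3]}-subj{index // block:02d}"


def generate_ictal(spec: SynthSpec, index: int) -> EEGRecord:
    """One ictal-like record, deterministic given ``(spec.seed, index)``."""
    rng = _rng(spec, "ictal", index)
    t = np.arange(spec.n_samples) / spec.fs
    f0 = rng.uniform(*spec.ictal_freq_range)
    phase = rng.uniform(0, 2 * np.pi, size=3)
    # fundamental plus decaying 2nd/3rd harmonics
    wave = np.zeros_like(t)
    for h, gain in enumerate((1.0, 0.45, 0.2), start=1):
        wave += gain * np.sin(2 * np.pi * h * f0 * t + phase[h - 1])
    # slow amplitude modulation (0.2-0.5 Hz), never fully suppressing
    fm = rng.uniform(0.2, 0.5)
    envelope = 1.0 + 0.35 * np.sin(2 * np.pi * fm * t + rng.uniform(0, 2 * np.pi))
    signal = spec.ictal_amplitude * envelope * wave
    rhythm_rms = float(np.sqrt(np.mean(signal**2)))
    noise = rng.standard_normal(spec.n_samples) * (0.15 * rhythm_rms)
    return EEGRecord(
        record_id=f"ict{index:04d}",
        samples=signal + noise,
        fs=spec.fs,
        label="ictal",
        group_id=_group_id("ictal", index, spec.n_per_class),
    )


def generate_interictal(spec: SynthSpec, index: int) -> EEGRecord:
    """One interictal-like record, deterministic given ``(spec.seed, index)``."""
    rng = _rng(spec, "interictal", index)
    n = spec.n_samples
    t = np.arange(n) / spec.fs
    # 1/f-shaped coloured noise via spectral shaping of white noise
    white = rng.standard_normal(n)
    spec_w = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / spec.fs)
    shaping = np.ones_like(freqs)
    nonzero = freqs > 0
    shaping[nonzero] = 1.0 / np.sqrt(freqs[nonzero])
    shaping[0] = 0.0  # no DC drift
    pink = np.fft.irfft(spec_w * shaping, n=n)
    rms = np.sqrt(np.mean(pink**2))
    pink = pink / rms if rms > 0 else pink
    # weak alpha rhythm
    fa = rng.uniform(8.0, 12.0)
    alpha = 0.4 * np.sin(2 * np.pi * fa * t + rng.uniform(0, 2 * np.pi))
    signal = spec.interictal_amplitude * 0.5 * (pink + alpha)
    return EEGRecord(
        record_id=f"int{index:04d}",
        samples=signal,
        fs=spec.fs,
        label="interictal",
        group_id=_group_id("interictal", index, spec.n_per_class),
    )


def generate_dataset(spec: SynthSpec) -> list[EEGRecord]:
    """Balanced, interleaved dataset of ``2 * n_per_class`` records."""
    records: list[EEGRecord] = []
    for i in range(spec.n_per_class):
        records.append(generate_ictal(spec, i))
        records.append(generate_interictal(spec, i))
    return records
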