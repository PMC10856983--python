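"""Record -> network-input pipeline: resample, window, CWT, normalize.

A raw record of L0 samples is linearly resampled so that windows of ``w``
samples at overlap fraction ``o`` tile it exactly:

    h = round(w * (1 - o))            (hop, round half away from zero)
    n = round((L0 - w) / h) + 1       (number of windows)
    resampled_len = w + (n - 1) * h

With the reference configuration (L0 = 4097, w = 868, o = 1/3) this yields
h = 579 and exactly n = 7 windows on a 4342-sample resampled signal.

Each window is transformed with a frequency-domain analytic CWT on a
log-spaced scale grid, the coefficient magnitudes are taken, and each
window's scalogram is independently min-max normalized to [0, 1]:

    C_N = (|C| - Cmin) / (Cmax - Cmin)

The per-record result is a stack of shape (n_scales, w, n); the reference
configuration produces 233 x 868 x 7.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import wavelets
from .signal_io import FS_UNSPECIFIED, EEGRecord

DEFAULT_N_SCALES = 233
#: lowest resolvable frequency: about two oscillation cycles per window
MIN_CYCLES_PER_WINDOW = 2.0


def _round_half_away(x: float) -> int:
    """Round half away from zero (platform-independent, unlike banker's)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class WindowingSpec:
    """A fully resolved windowing plan; build with :func:`plan_windows`."""

    window_len: int
    overlap: float
    hop: int
    n_windows: int
    resampled_len: int

    def __post_init__(self) -> None:
        if self.window_len < 2 or self.hop < 1 or self.n_windows < 1:
            raise ValueError("degenerate windowing plan")
        if self.resampled_len != self.window_len + (self.n_windows - 1) * self.hop:
            raise ValueError("windows do not tile the resampled signal")


@dataclass(frozen=True)
class WaveletSpec:
    """Mother wavelet family plus the sampling-rate interpretation.

    ``fs_mode="physical"`` labels scales in Hz using the record's sampling
    rate; ``"unspecified"`` works in normalized frequency (cycles/sample).
    The transform itself is identical — fs only affects how the scale range
    is reported.
    """

    family: str = "bump"
    fs_mode: str = "unspecified"

    def __post_init__(self) -> None:
        if self.family not in wavelets.FAMILIES:
            raise ValueError(
                f"unknown wavelet family {self.family!r}; "
                f"choose from {wavelets.FAMILIES}"
            )
        if self.fs_mode not in ("physical", "unspecified"):
            raise ValueError("fs_mode must be 'physical' or 'unspecified'")


@dataclass
class Scalogram:
    """Normalized |CWT| of one window: entries in [0, 1], scales ascending."""

    values: np.ndarray  # (n_scales, window_len)
    scales: np.ndarray
    window_index: int


@dataclass
class ScalogramStack:
    """All windows of one record, shape (n_scales, window_len, n_windows)."""

    record_id: str
    tensor: np.ndarray
    label: str


def plan_windows(signal_len: int, window_len: int, overlap: float) -> WindowingSpec:
    """Resolve (signal length, window length, overlap) into a tiling plan."""
    if window_len < 2:
        raise ValueError("window_len must be >= 2")
    if not (0 <= overlap < 1):
        raise ValueError("overlap must be in [0, 1)")
    if signal_len < window_len:
        raise ValueError(
            f"signal of {signal_len} samples shorter than one {window_len}-sample window"
        )
    hop = _round_half_away(window_len * (1.0 - overlap))
    n = _round_half_away((signal_len - window_len) / hop) + 1
    return WindowingSpec(
        window_len=window_len,
        overlap=overlap,
        hop=hop,
        n_windows=n,
        resampled_len=window_len + (n - 1) * hop,
    )


def resample(samples: np.ndarray, target_len: int) -> np.ndarray:
    """Linear interpolation onto `target_len` points; endpoints preserved."""
    x = np.asarray(samples, dtype=np.float64)
    if x.size == 0:
        raise ValueError("cannot resample an empty signal")
    if target_len < 2:
        raise ValueError("target_len must be >= 2")
    if target_len == x.size:
        return x.copy()
    old = np.linspace(0.0, x.size - 1.0, x.size)
    new = np.linspace(0.0, x.size - 1.0, target_len)
    return np.interp(new, old, x)


def segment(samples: np.ndarray, spec: WindowingSpec) -> list[np.ndarray]:
    """Slice into `spec.n_windows` windows of `spec.window_len` samples."""
    x = np.asarray(samples)
    if x.size != spec.resampled_len:
        raise ValueError(
            f"expected {spec.resampled_len} samples, got {x.size}; resample first"
        )
    return [
        x[k * spec.hop : k * spec.hop + spec.window_len]
        for k in range(spec.n_windows)
    ]


def scale_grid(
    family: str, window_len: int, n_scales: int = DEFAULT_N_SCALES
) -> np.ndarray:
    """Log-spaced scales spanning ~2 cycles/window up to Nyquist.

    Scales are ascending, i.e. center frequencies descend from 0.5
    cycles/sample down to MIN_CYCLES_PER_WINDOW / window_len.
    """
    if n_scales < 2:
        raise ValueError("n_scales must be >= 2")
    wc = wavelets.center_omega(family)
    f_hi = 0.5  # Nyquist in cycles/sample
    f_lo = MIN_CYCLES_PER_WINDOW / window_len
    s_min = wc / (2.0 * np.pi * f_hi)
    s_max = wc / (2.0 * np.pi * f_lo)
    return np.geomspace(s_min, s_max, n_scales)


def cwt_scalogram(
    window: np.ndarray,
    wavelet: WaveletSpec | str,
    n_scales: int = DEFAULT_N_SCALES,
    fs: float | str = FS_UNSPECIFIED,
) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude CWT of one window.

    The window is transformed to the frequency domain, multiplied by the
    analytic wavelet's response at each scale, inverted, and the magnitude
    taken.  Returns ``(|C|, scales)`` with ``|C|`` of shape
    ``(n_scales, len(window))``.
    """
    if isinstance(wavelet, str):
        wavelet = WaveletSpec(family=wavelet)
    x = np.asarray(window, dtype=np.float64)
    if x.ndim != 1 or x.size < 8:
        raise ValueError("window must be 1-D with at least 8 samples")
    scales = scale_grid(wavelet.family, x.size, n_scales)
    omega = 2.0 * np.pi * np.fft.fftfreq(x.size)  # rad/sample
    X = np.fft.fft(x)
    psi = np.stack([wavelets.psi_hat(wavelet.family, s * omega) for s in scales])
    coeffs = np.fft.ifft(X[None, :] * psi, axis=1)
    return np.abs(coeffs), scales


def normalize_scalogram(C: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1]; a constant matrix maps to all zeros."""
    C = np.asarray(C, dtype=np.float64)
    if not np.all(np.isfinite(C)):
        raise ValueError("scalogram contains non-finite entries")
    cmin, cmax = C.min(), C.max()
    if cmax == cmin:
        return np.zeros_like(C)
    return (C - cmin) / (cmax - cmin)


def resize_bilinear(image: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Bilinear resize of a 2-D array (optional stage, off by default)."""
    img = np.asarray(image, dtype=np.float64)
    h, w = img.shape
    th, tw = shape
    rows = np.linspace(0.0, h - 1.0, th)
    cols = np.linspace(0.0, w - 1.0, tw)
    r0 = np.clip(np.floor(rows).astype(int), 0, h - 2) if h > 1 else np.zeros(th, int)
    c0 = np.clip(np.floor(cols).astype(int), 0, w - 2) if w > 1 else np.zeros(tw, int)
    fr = (rows - r0)[:, None]
    fc = (cols - c0)[None, :]
    a = img[np.ix_(r0, c0)]
    b = img[np.ix_(r0, np.minimum(c0 + 1, w - 1))]
    c = img[np.ix_(np.minimum(r0 + 1, h - 1), c0)]
    d = img[np.ix_(np.minimum(r0 + 1, h - 1), np.minimum(c0 + 1, w - 1))]
    return a * (1 - fr) * (1 - fc) + b * (1 - fr) * fc + c * fr * (1 - fc) + d * fr * fc


def preprocess_record(
    record: EEGRecord,
    window_len: int = 868,
    overlap: float = 1.0 / 3.0,
    wavelet: WaveletSpec | str = "bump",
    n_scales: int = DEFAULT_N_SCALES,
    resize_to: tuple[int, int] | None = None,
) -> ScalogramStack:
    """Full pipeline for one record: resample -> segment -> CWT -> normalize."""
    if isinstance(wavelet, str):
        wavelet = WaveletSpec(family=wavelet)
    plan = plan_windows(len(record), window_len, overlap)
    x = resample(record.samples, plan.resampled_len)
    windows = segment(x, plan)
    fs = record.fs if wavelet.fs_mode == "physical" else FS_UNSPECIFIED
    mats = []
    for w in windows:
        C, _ = cwt_scalogram(w, wavelet, n_scales, fs)
        C = normalize_scalogram(C)
        if resize_to is not None:
            C = resize_bilinear(C, resize_to)
        mats.append(C)
    tensor = np.stack(mats, axis=-1)  # (n_scales, w, n)
    return ScalogramStack(record_id=record.record_id, tensor=tensor, label=record.label)


def preprocess_dataset(
    records: list[EEGRecord], **kwargs
) -> list[ScalogramStack]:
    """Apply :func:`preprocess_record` to every record."""
    return [preprocess_record(r, **kwargs) for r in records]
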