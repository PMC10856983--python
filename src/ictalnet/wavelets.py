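"""Analytic mother wavelets in the frequency domain.

Each family is defined by its frequency response psi_hat(omega) on the
positive half-axis (analytic wavelets: psi_hat = 0 for omega <= 0), with the
standard parameterizations:

``morlet``  exp(-(omega - mu)^2 / 2), mu = 6
``bump``    exp(1 - 1 / (1 - ((omega - mu)/sigma)^2)) on |omega - mu| < sigma,
            mu = 5, sigma = 0.6
``gmw``     generalized Morse, c * omega^beta * exp(-omega^gamma),
            gamma = 3, beta = 60, peak normalized to 1
``cmhat``   complex (analytic) Mexican hat, omega^2 * exp(-omega^2 / 2)
``hhhat``   Hilbert analytic function of the Hermitian hat,
            omega * (1 + omega) * exp(-omega^2 / 2)

The center (peak) angular frequency of each family, used to map scales to
frequencies, is found numerically from psi_hat.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

FAMILIES = ("gmw", "morlet", "bump", "cmhat", "hhhat")

_MORLET_MU = 6.0
_BUMP_MU = 5.0
_BUMP_SIGMA = 0.6
_GMW_GAMMA = 3.0
_GMW_BETA = 60.0


def psi_hat(family: str, omega: np.ndarray) -> np.ndarray:
    """Frequency response of the analytic mother wavelet at `omega` [rad]."""
    w = np.asarray(omega, dtype=np.float64)
    pos = w > 0
    out = np.zeros_like(w)
    if family == "morlet":
        out[pos] = np.exp(-0.5 * (w[pos] - _MORLET_MU) ** 2)
    elif family == "bump":
        u = (w - _BUMP_MU) / _BUMP_SIGMA
        inside = pos & (np.abs(u) < 1)
        out[inside] = np.exp(1.0 - 1.0 / (1.0 - u[inside] ** 2))
    elif family == "gmw":
        # evaluate in log space; peak at omega_c = (beta/gamma)^(1/gamma)
        wc = (_GMW_BETA / _GMW_GAMMA) ** (1.0 / _GMW_GAMMA)
        log_peak = _GMW_BETA * np.log(wc) - wc**_GMW_GAMMA
        lw = np.log(w[pos])
        out[pos] = np.exp(_GMW_BETA * lw - w[pos] ** _GMW_GAMMA - log_peak)
    elif family == "cmhat":
        # peak value 2/e at omega = sqrt(2); normalize peak to 1
        out[pos] = w[pos] ** 2 * np.exp(-0.5 * w[pos] ** 2) / (2.0 / np.e)
    elif family == "hhhat":
        out[pos] = w[pos] * (1.0 + w[pos]) * np.exp(-0.5 * w[pos] ** 2)
        out /= _hhhat_peak()
    else:
        raise ValueError(f"unknown wavelet family {family!r}; choose from {FAMILIES}")
    return out


@lru_cache(maxsize=None)
def _hhhat_peak() -> float:
    w = np.linspace(1e-4, 10.0, 200_001)
    return float(np.max(w * (1.0 + w) * np.exp(-0.5 * w**2)))


@lru_cache(maxsize=None)
def center_omega(family: str) -> float:
    """Peak angular frequency of psi_hat, found on a fine grid."""
    if family == "morlet":
        return _MORLET_MU
    if family == "bump":
        return _BUMP_MU
    if family == "gmw":
        return float((_GMW_BETA / _GMW_GAMMA) ** (1.0 / _GMW_GAMMA))
    grid = np.linspace(1e-4, 25.0, 500_001)
    return float(grid[int(np.argmax(psi_hat(family, grid)))])


def center_frequency(family: str, scale: float) -> float:
    """Center frequency, in cycles/sample, of the wavelet at `scale`."""
    return center_omega(family) / (2.0 * np.pi * scale)
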