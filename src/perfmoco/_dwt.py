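"""Periodized orthogonal discrete wavelet transform (Daubechies, 5 vanishing
moments).

Only what the component-labeling step needs: multilevel analysis of short
1D signals, energy bookkeeping per band, and reconstruction with selected
bands zeroed. Periodization keeps the transform orthogonal for even-length
signals, so coefficient energy equals signal energy.
"""

from __future__ import annotations

import numpy as np

# Daubechies-5 (maximum phase) reconstruction low-pass filter.
_DB5_REC_LO = np.array(
    [
        0.160102397974125,
        0.6038292697974729,
        0.7243085284385744,
        0.13842814590110342,
        -0.24229488706619015,
        -0.03224486958502952,
        0.07757149384006515,
        -0.006241490213011705,
        -0.012580751999015526,
        0.003335725285001549,
    ]
)

DEC_LO = _DB5_REC_LO[::-1].copy()
# quadrature mirror: g[n] = (-1)^n h[N-1-n]
DEC_HI = np.power(-1.0, np.arange(DEC_LO.size)) * DEC_LO[::-1]


def _analysis_step(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = x.size
    idx = (2 * np.arange(n // 2)[:, None] + np.arange(DEC_LO.size)[None, :]) % n
    windows = x[idx]
    return windows @ DEC_LO, windows @ DEC_HI


def _synthesis_step(a: np.ndarray, d: np.ndarray) -> np.ndarray:
    n = 2 * a.size
    x = np.zeros(n)
    for i in range(a.size):
        idx = (2 * i + np.arange(DEC_LO.size)) % n
        np.add.at(x, idx, a[i] * DEC_LO + d[i] * DEC_HI)
    return x


def max_level(n: int) -> int:
    level = 0
    while n % 2 == 0 and n >= 2 * DEC_LO.size:
        n //= 2
        level += 1
    return level


def wavedec(x: np.ndarray, level: int | None = None) -> list[np.ndarray]:
    """Multilevel analysis -> [a_L, d_L, d_{L-1}, ..., d_1].

    Inputs are symmetrically extended to the next power of two so that
    several dyadic levels exist even for short, odd-length signals.
    """
    x = np.asarray(x, dtype=float)
    n_pad = 1 << max(int(np.ceil(np.log2(max(x.size, 2)))), 1)
    if n_pad > x.size:
        reflect = x[::-1]
        ext = np.concatenate([x, np.tile(reflect, 1 + (n_pad - x.size) // x.size)])
        x = ext[:n_pad]
    feasible = max_level(x.size)
    if level is None:
        level = feasible
    level = min(level, feasible)
    if level < 1:
        return [x.copy()]
    details = []
    a = x
    for _ in range(level):
        a, d = _analysis_step(a)
        details.append(d)
    return [a] + details[::-1]


def waverec(coeffs: list[np.ndarray]) -> np.ndarray:
    a = coeffs[0]
    for d in coeffs[1:]:
        a = _synthesis_step(a, d)
    return a


def band_energies(coeffs: list[np.ndarray]) -> np.ndarray:
    """Energy per band, ordered [approx, d_L, ..., d_1]."""
    return np.array([float(np.sum(c * c)) for c in coeffs])


def coarse_reconstruction(x: np.ndarray, n_fine_levels: int = 2) -> np.ndarray:
    """Reconstruct with the ``n_fine_levels`` finest detail bands zeroed."""
    n = np.asarray(x).size
    coeffs = wavedec(x)
    for i in range(1, min(n_fine_levels, len(coeffs) - 1) + 1):
        coeffs[-i] = np.zeros_like(coeffs[-i])
    return waverec(coeffs)[:n]
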