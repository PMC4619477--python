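"""Multilevel Haar decomposition and trace denoising.

A chromatogram channel f(t) is split into a smooth approximation and
high-frequency detail at each level, f(t) = A_n + sum_i D_i, with every
component re-expressed at the original resolution so the identity holds
elementwise. Denoising keeps only the level-n approximation (default n = 3):
the detail sub-signals carry the baseline noise and are discarded outright
rather than thresholded.

The transform is the orthonormal Haar filter bank (PyWavelets, periodized),
so squared signal energy splits exactly between approximation and detail
coefficients at every level. Signals whose length is not a multiple of
2**levels are symmetric-padded; the pad is dropped after reconstruction so
output length always equals input length and peak scan indices stay valid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .types import ChromatogramTrace

_WAVELET = "haar"
_MODE = "periodization"


@dataclass(frozen=True)
class WaveletDecomposition:
    """Additive multilevel decomposition, all components at full resolution."""

    original: np.ndarray
    approximations: list[np.ndarray]
    details: list[np.ndarray]

    @property
    def levels(self) -> int:
        return len(self.approximations)


def _pad(signal: np.ndarray, levels: int) -> tuple[np.ndarray, int]:
    block = 2**levels
    n = len(signal)
    pad = (-n) % block
    if pad:
        signal = np.pad(signal, (0, pad), mode="symmetric")
    return signal, n


def _upcast(coeffs: np.ndarray, levels: int) -> np.ndarray:
    """Re-express level-`levels` coefficients at original resolution by
    inverting with zero complements."""
    x = coeffs
    for _ in range(levels):
        x = pywt.idwt(x, None, _WAVELET, mode=_MODE)
    return x


def haar_decompose(signal, levels: int) -> WaveletDecomposition:
    """Decompose ``signal`` into ``levels`` Haar approximation/detail pairs.

    Raises ValueError if the signal is shorter than 2**levels.
    """
    signal = np.asarray(signal, dtype=float)
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if len(signal) < 2**levels:
        raise ValueError(
            f"signal length {len(signal)} too short for {levels} levels "
            f"(needs >= {2 ** levels})"
        )
    padded, n = _pad(signal, levels)
    approximations: list[np.ndarray] = []
    details: list[np.ndarray] = []
    a = padded
    for level in range(1, levels + 1):
        ca, cd = pywt.dwt(a, _WAVELET, mode=_MODE)
        approximations.append(_upcast(ca, level)[:n])
        d_full = pywt.idwt(None, cd, _WAVELET, mode=_MODE)
        details.append(_upcast(d_full, level - 1)[:n])
        a = ca
    return WaveletDecomposition(
        original=signal, approximations=approximations, details=details
    )


def denoise_channel(signal, levels: int = 3) -> np.ndarray:
    """Return the level-``levels`` approximation of ``signal``, clipped at 0.

    Same length as the input; all high-frequency detail is discarded.
    """
    signal = np.asarray(signal, dtype=float)
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if len(signal) < 2**levels:
        raise ValueError(
            f"signal length {len(signal)} too short for {levels} levels"
        )
    padded, n = _pad(signal, levels)
    a = padded
    for _ in range(levels):
        a, _cd = pywt.dwt(a, _WAVELET, mode=_MODE)
    return np.clip(_upcast(a, levels)[:n], 0.0, None)


def denoise_trace(trace: ChromatogramTrace, levels: int = 3) -> ChromatogramTrace:
    """Denoise all four channels of a trace; base calls and scans unchanged."""
    return ChromatogramTrace(
        sample_id=trace.sample_id,
        channels={b: denoise_channel(s, levels) for b, s in trace.channels.items()},
        called_bases=trace.called_bases,
        peak_scans=trace.peak_scans.copy(),
    )
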