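"""Shared spectral helpers: canonical frequency bands and band power.

The analysis chain works with three canonical bands — alpha (8–13 Hz),
beta (13–30 Hz) and gamma (30–80 Hz) — and quantifies them either per
short frame (real-time detection path) or with Welch's method over longer
stretches (offline comparisons, 1 s windows with 0.5 s overlap).
"""

from __future__ import annotations

import functools

import numpy as np
from scipy import signal


@functools.lru_cache(maxsize=64)
def bandpass_sos(lo: float, hi: float, fs: float, order: int = 4):
    """Cached Butterworth band-pass design (second-order sections)."""
    return signal.butter(order, (lo, hi), btype="bandpass", fs=fs,
                         output="sos")


@functools.lru_cache(maxsize=16)
def highpass_sos(cutoff: float, fs: float, order: int = 2):
    """Cached Butterworth high-pass design."""
    return signal.butter(order, cutoff, btype="highpass", fs=fs,
                         output="sos")


def all_welch_band_powers(x: np.ndarray, fs: float,
                          bands: dict[str, tuple[float, float]] | None = None
                          ) -> dict[str, float]:
    """All band powers from one Welch PSD (1 s windows, 0.5 s overlap).

    Same estimator as `welch_band_power`, computed once for every band —
    the generator calibrates against this so that contract measurements
    and calibration agree bin for bin.
    """
    bands = bands or BANDS
    nperseg = int(round(fs))
    freqs, pxx = signal.welch(x, fs=fs, nperseg=nperseg,
                              noverlap=nperseg // 2)
    df = freqs[1] - freqs[0]
    return {name: float(pxx[(freqs >= lo) & (freqs < hi)].sum() * df)
            for name, (lo, hi) in bands.items()}

#: Canonical analysis bands in Hz.
BANDS: dict[str, tuple[float, float]] = {
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 80.0),
}

BAND_NAMES = tuple(BANDS)


def _check_band(band: tuple[float, float], fs: float) -> None:
    lo, hi = band
    if lo >= hi:
        raise ValueError(f"degenerate band ({lo}, {hi})")
    if lo <= 0 or hi >= fs / 2:
        raise ValueError(f"band ({lo}, {hi}) outside (0, {fs / 2}) Hz")


def band_power(frame: np.ndarray, band: tuple[float, float], fs: float) -> np.ndarray:
    """Band power (mV^2) of the last axis of `frame` via a Hann periodogram.

    Works on a single frame or a stack of frames; integrates the one-sided
    periodogram over `band` so that, by Parseval, summing over disjoint
    bands recovers the signal power up to spectral leakage.
    """
    _check_band(band, fs)
    freqs, pxx = signal.periodogram(frame, fs=fs, window="hann", axis=-1)
    sel = (freqs >= band[0]) & (freqs < band[1])
    df = freqs[1] - freqs[0]
    return pxx[..., sel].sum(axis=-1) * df


def welch_band_power(
    x: np.ndarray,
    band: tuple[float, float],
    fs: float,
    nperseg_s: float = 1.0,
    overlap_s: float = 0.5,
) -> float:
    """Welch-estimate band power (mV^2) with 1 s windows, 0.5 s overlap."""
    _check_band(band, fs)
    nperseg = int(round(nperseg_s * fs))
    noverlap = int(round(overlap_s * fs))
    freqs, pxx = signal.welch(x, fs=fs, nperseg=nperseg, noverlap=noverlap)
    sel = (freqs >= band[0]) & (freqs < band[1])
    return float(pxx[sel].sum() * (freqs[1] - freqs[0]))


def welch_psd(x: np.ndarray, fs: float, nperseg_s: float = 1.0, overlap_s: float = 0.5):
    """Welch PSD with the package's standard 1 s / 0.5 s windowing."""
    nperseg = int(round(nperseg_s * fs))
    noverlap = int(round(overlap_s * fs))
    return signal.welch(x, fs=fs, nperseg=nperseg, noverlap=noverlap)
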