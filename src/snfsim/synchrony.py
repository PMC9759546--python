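"""Inter-hemispheric phase synchrony of hippocampal LFP.

The synchrony index between two signals is the phase-locking value

    R = | < e^{i * dtheta} > |

where dtheta is the per-sample phase difference and the average runs over a
window. R = 1 means perfect (possibly lagged) locking; for uniformly random
phase differences over N samples E[R] ~ sqrt(pi) / (2 sqrt(N)). Windows with
R at or above a hyper-synchrony threshold (default 0.7, the paroxysmal
range) are classified as hyper-synchronized.

Phase is extracted by band-pass filtering (default broad 1-48 Hz) followed
by the analytic-signal (Hilbert) phase, which makes R independent of signal
amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal, stats

from .spectral import bandpass_sos

DEFAULT_BAND = (1.0, 48.0)
HYPER_THRESHOLD = 0.7

#: Post-filter edge exclusion when windowing a full record, seconds.
EDGE_EXCLUDE_S = 0.5


@dataclass
class PhaseSeries:
    """Wrapped instantaneous phase (radians, in (-pi, pi]) of one channel."""

    phase: np.ndarray
    fs: float
    band: tuple[float, float] = DEFAULT_BAND
    source: str = ""
    undefined: bool = False  # set when the source signal was identically zero

    def unwrapped(self) -> np.ndarray:
        return np.unwrap(self.phase)

    def __len__(self) -> int:
        return len(self.phase)


@dataclass
class SynchronySeries:
    """Per-window synchrony index R with window bookkeeping."""

    R: np.ndarray
    window_starts: np.ndarray  # sample indices
    window_len: int            # samples
    fs: float

    @property
    def window_times(self) -> np.ndarray:
        return self.window_starts / self.fs


@dataclass
class SynchronyConfig:
    band: tuple[float, float] = DEFAULT_BAND
    window_len_s: float = 1.0
    hop_s: float = 0.5
    hyper_threshold: float = HYPER_THRESHOLD

    def __post_init__(self) -> None:
        if not 0.0 < self.hyper_threshold <= 1.0:
            raise ValueError("hyper_threshold must be in (0, 1]")


def instantaneous_phase(
    x: np.ndarray, band: tuple[float, float], fs: float, source: str = ""
) -> PhaseSeries:
    """Band-pass filter then extract analytic-signal phase.

    Scaling the signal by any k > 0 leaves the phase unchanged. An all-zero
    signal has no defined phase and is flagged.
    """
    x = np.asarray(x, dtype=float)
    if band[0] <= 0 or band[1] >= fs / 2:
        raise ValueError(f"band {band} outside (0, {fs / 2}) Hz")
    if not np.any(x):
        return PhaseSeries(np.zeros_like(x), fs, band, source, undefined=True)
    sos = bandpass_sos(band[0], band[1], fs)
    filt = signal.sosfiltfilt(sos, x)
    phase = np.angle(signal.hilbert(filt))
    return PhaseSeries(phase, fs, band, source)


def synchrony_index(
    phase_a: PhaseSeries | np.ndarray,
    phase_b: PhaseSeries | np.ndarray,
    windows: Sequence[tuple[int, int]],
    fs: float | None = None,
) -> SynchronySeries:
    """Phase-locking index R = |<e^{i dtheta}>| per (start, length) window.

    Windows are given in samples. R is invariant to a constant phase offset
    (lag-insensitive) and to circular relabeling of samples within a window.
    """
    if isinstance(phase_a, PhaseSeries):
        fs = phase_a.fs
        pa, pb = phase_a.phase, phase_b.phase
    else:
        pa, pb = np.asarray(phase_a), np.asarray(phase_b)
        if fs is None:
            raise ValueError("fs required when passing raw phase arrays")
    if len(pa) != len(pb):
        raise ValueError("phase series lengths differ")
    z = np.exp(1j * (pa - pb))
    Rs, starts = [], []
    for start, length in windows:
        if length < 10:
            raise ValueError(f"window of {length} samples too short (< 10)")
        if start < 0 or start + length > len(z):
            raise ValueError("window outside series")
        Rs.append(np.abs(np.mean(z[start:start + length])))
        starts.append(start)
    return SynchronySeries(np.asarray(Rs), np.asarray(starts),
                           int(windows[0][1]) if windows else 0, fs)


def sliding_windows(n_samples: int, fs: float,
                    config: SynchronyConfig) -> list[tuple[int, int]]:
    """Standard sliding windows, excluding filter-edge margins."""
    win = int(round(config.window_len_s * fs))
    hop = int(round(config.hop_s * fs))
    margin = int(round(EDGE_EXCLUDE_S * fs))
    starts = range(margin, n_samples - margin - win + 1, hop)
    return [(s, win) for s in starts]


def record_synchrony(record, chan_a: str, chan_b: str,
                     config: SynchronyConfig | None = None) -> SynchronySeries:
    """Convenience wrapper: R series between two channels of an LFPRecord."""
    config = config or SynchronyConfig()
    pa = instantaneous_phase(record.channel(chan_a), config.band, record.fs, chan_a)
    pb = instantaneous_phase(record.channel(chan_b), config.band, record.fs, chan_b)
    wins = sliding_windows(record.n_samples, record.fs, config)
    return synchrony_index(pa, pb, wins)


def classify_windows(series: SynchronySeries,
                     hyper_threshold: float = HYPER_THRESHOLD) -> np.ndarray:
    """Label each window 'hyper' iff R >= threshold, else 'normal'."""
    return np.where(series.R >= hyper_threshold, "hyper", "normal")


def synchrony_distribution(
    series_by_condition: dict[str, SynchronySeries | np.ndarray],
    grid: np.ndarray | None = None,
) -> dict:
    """Empirical CDFs of R per condition plus pairwise KS distances.

    Requires >= 30 windows per condition. Returns a dict with a common
    ``grid``, per-condition ``cdf`` arrays, and ``ks`` distances keyed by
    condition pairs.
    """
    values = {}
    for cond, s in series_by_condition.items():
        r = s.R if isinstance(s, SynchronySeries) else np.asarray(s)
        if len(r) < 30:
            raise ValueError(f"condition {cond!r} has {len(r)} < 30 windows")
        values[cond] = np.sort(r)
    if grid is None:
        grid = np.linspace(0.0, 1.0, 201)
    cdfs = {c: np.searchsorted(v, grid, side="right") / len(v)
            for c, v in values.items()}
    ks = {}
    conds = list(values)
    for i, a in enumerate(conds):
        for b in conds[i + 1:]:
            stat = stats.ks_2samp(values[a], values[b])
            ks[(a, b)] = float(stat.statistic)
    return {"grid": grid, "cdf": cdfs, "ks": ks}
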