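"""Core containers for multichannel LFP recordings and seizure ground truth.

Conventions used throughout the package:

* signals are in millivolts, time in seconds, sampling rate in Hz;
* a recording is a ``(n_channels, n_samples)`` float array plus ordered
  channel labels such as ``HPC-L`` (left hippocampus) or ``CTX-R`` (right
  cortex);
* seizure ground truth is a list of ``(onset_s, offset_s, laterality)``
  intervals plus motion-artifact intervals, both on the recording timeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

DEFAULT_FS = 500.0
DEFAULT_CHANNELS = ("HPC-L", "HPC-R", "CTX-L", "CTX-R")

#: Highest band edge used anywhere in the analysis chain (gamma upper edge).
MAX_ANALYSIS_HZ = 80.0

LATERALITIES = ("left", "right", "bilateral")


@dataclass
class LFPRecord:
    """Multichannel local-field-potential recording in mV.

    Parameters
    ----------
    samples
        Array of shape ``(n_channels, n_samples)``, millivolts.
    fs
        Sampling rate in Hz. Must exceed twice the highest analysis band
        edge (80 Hz) so that alpha/beta/gamma band powers are resolvable.
    channel_labels
        Ordered channel roles, e.g. ``("HPC-L", "HPC-R", "CTX-L", "CTX-R")``.
    start_time
        Timeline origin in seconds.
    """

    samples: np.ndarray
    fs: float = DEFAULT_FS
    channel_labels: tuple[str, ...] = DEFAULT_CHANNELS
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (n_channels, n_samples) array")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.samples.shape[0]} channels"
            )
        if self.fs <= 2 * MAX_ANALYSIS_HZ:
            raise ValueError(
                f"fs={self.fs} Hz cannot resolve the {MAX_ANALYSIS_HZ} Hz "
                "analysis band edge"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain NaN or Inf")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Return the 1-D signal for a channel label."""
        try:
            idx = self.channel_labels.index(label)
        except ValueError as exc:
            raise KeyError(f"no channel {label!r}") from exc
        return self.samples[idx]

    def copy(self) -> "LFPRecord":
        return LFPRecord(
            self.samples.copy(), self.fs, tuple(self.channel_labels), self.start_time
        )


@dataclass
class SeizureEvent:
    onset: float
    offset: float
    laterality: str = "bilateral"

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError(f"offset {self.offset} <= onset {self.onset}")
        if self.laterality not in LATERALITIES:
            raise ValueError(f"laterality must be one of {LATERALITIES}")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class SeizureGroundTruth:
    """Truth labels for ictal events and motion-artifact intervals."""

    events: list[SeizureEvent] = field(default_factory=list)
    artifact_intervals: list[tuple[float, float]] = field(default_factory=list)
    duration: float | None = None

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.onset)
        for a, b in zip(self.events, self.events[1:]):
            if b.onset < a.offset:
                raise ValueError(
                    f"overlapping events: ({a.onset}, {a.offset}) and "
                    f"({b.onset}, {b.offset})"
                )
        if self.duration is not None:
            for e in self.events:
                if e.onset < 0 or e.offset > self.duration:
                    raise ValueError("event outside record duration")


@dataclass
class IctalParams:
    """Parameters shaping a synthetic ictal (seizure) segment.

    ``band_gain`` gives the target alpha/beta/gamma band-power multipliers
    relative to the generator's reference baseline; the detector's trigger
    rule is power greater than twice baseline, so gains >= 2 make a segment
    detectable by construction. ``synchrony_target`` is the desired
    inter-hippocampal phase-locking index R in [0, 1].
    """

    spike_wave_rate: float = 6.0
    band_gain: tuple[float, float, float] = (3.0, 3.0, 3.0)
    synchrony_target: float = 0.9
    phase_lag: float = 0.0
    spike_amp_sd: float = 5.0  # spike amplitude as multiple of baseline SD

    def __post_init__(self) -> None:
        if not 0.0 <= self.synchrony_target <= 1.0:
            raise ValueError(
                f"synchrony_target {self.synchrony_target} outside [0, 1]"
            )
        if self.spike_wave_rate <= 0:
            raise ValueError("spike_wave_rate must be positive")


def validate_schedule(events: Sequence[SeizureEvent], duration_s: float) -> None:
    """Reject overlapping or out-of-range seizure schedules."""
    ordered = sorted(events, key=lambda e: e.onset)
    for e in ordered:
        if e.onset < 0 or e.offset > duration_s:
            raise ValueError(
                f"event ({e.onset}, {e.offset}) outside record [0, {duration_s}]"
            )
    for a, b in zip(ordered, ordered[1:]):
        if b.onset < a.offset:
            raise ValueError("schedule contains overlapping events")
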