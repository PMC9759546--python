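"""Recording and event I/O.

The primary on-disk format is plain text: a CSV with one column per channel
(header row carries channel labels; sampling rate and start time live in a
JSON sidecar together with the seizure/artifact ground truth). EDF files
can be read when `mne` is installed (the ``edf`` extra); detection results
are written as JSON and as a BED-like tab-delimited interval file whose
first column is the channel label with 0-based half-open sample intervals.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .detection import DetectionResult
from .records import LFPRecord, SeizureEvent, SeizureGroundTruth


def write_csv(record: LFPRecord, path, truth: SeizureGroundTruth | None = None
              ) -> None:
    """Write a recording as CSV plus a JSON sidecar (`<path>.json`)."""
    path = Path(path)
    header = ",".join(record.channel_labels)
    np.savetxt(path, record.samples.T, delimiter=",", header=header,
               comments="", fmt="%.6f")
    sidecar = {
        "fs": record.fs,
        "start_time": record.start_time,
        "channel_labels": list(record.channel_labels),
        "units": "mV",
    }
    if truth is not None:
        sidecar["events"] = [
            {"onset": e.onset, "offset": e.offset, "laterality": e.laterality}
            for e in truth.events
        ]
        sidecar["artifact_intervals"] = [list(i) for i in
                                         truth.artifact_intervals]
        sidecar["duration"] = truth.duration
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1))


def read_csv(path) -> tuple[LFPRecord, SeizureGroundTruth | None]:
    """Read a CSV recording and its JSON sidecar if present."""
    path = Path(path)
    with open(path) as fh:
        labels = tuple(fh.readline().strip().split(","))
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    fs, start, truth = 500.0, 0.0, None
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        fs = meta.get("fs", fs)
        start = meta.get("start_time", start)
        labels = tuple(meta.get("channel_labels", labels))
        if "events" in meta:
            truth = SeizureGroundTruth(
                events=[SeizureEvent(e["onset"], e["offset"],
                                     e.get("laterality", "bilateral"))
                        for e in meta["events"]],
                artifact_intervals=[tuple(i) for i in
                                    meta.get("artifact_intervals", [])],
                duration=meta.get("duration"),
            )
    rec = LFPRecord(np.atleast_2d(data.T), fs=fs, channel_labels=labels,
                    start_time=start)
    return rec, truth


def read_edf(path) -> LFPRecord:
    """Read an EDF recording (requires the ``edf`` extra / mne)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "reading EDF requires mne (pip install snfsim[edf])") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e3  # V -> mV
    return LFPRecord(data, fs=float(raw.info["sfreq"]),
                     channel_labels=tuple(raw.ch_names))


def read_record(path) -> tuple[LFPRecord, SeizureGroundTruth | None]:
    """Dispatch on extension: .edf via mne, anything else as CSV."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_edf(path), None
    return read_csv(path)


def write_detection_json(result: DetectionResult, path) -> None:
    payload = {
        "mode": result.mode,
        "triggers": [float(t) for t in result.triggers],
        "events": [
            {"onset": float(a), "offset": float(b), "channels": list(ch)}
            for a, b, ch in result.events
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def write_detection_bed(result: DetectionResult, path, fs: float) -> None:
    """BED-like intervals: channel label, 0-based half-open sample interval,
    then onset/offset in seconds."""
    lines = []
    for onset, offset, channels in result.events:
        for ch in channels or ("*",):
            lines.append(
                f"{ch}\t{int(round(onset * fs))}\t{int(round(offset * fs))}"
                f"\t{onset:.3f}\t{offset:.3f}"
            )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
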