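"""Report assembly: PSD comparisons, endpoint tables, reproducible bundles.

Everything here is plumbing around standard routines: Welch PSDs (1 s
windows, 0.5 s overlap), per-band means, and nonparametric group tests via
scipy. Reports are deterministic functions of their inputs (configs and
seeds are embedded), rendered as Markdown plus CSV tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import LFPRecord
from .spectral import BAND_NAMES, BANDS, welch_band_power


@dataclass
class AnalysisBundle:
    """References to per-module outputs plus provenance (configs, seeds)."""

    detection: dict | None = None
    synchrony: dict | None = None
    field_summary: dict | None = None
    thresholds: pd.DataFrame | None = None
    endpoints: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)

    def missing(self) -> list[str]:
        return [name for name in ("detection", "synchrony", "field_summary",
                                  "thresholds", "endpoints")
                if getattr(self, name) is None]


def psd_comparison(records_by_arm: dict[str, Sequence[LFPRecord]],
                   channel: str = "HPC-R") -> pd.DataFrame:
    """Per-band mean power per arm with Kruskal-Wallis tests across arms.

    Band power is computed per record with Welch's method (1 s windows,
    0.5 s overlap); returns a tidy frame of arm x band means plus one row
    of p-values when there are >= 2 arms with >= 2 records each.
    """
    if len(records_by_arm) < 2:
        raise ValueError("need at least two arms")
    fs_vals = {rec.fs for recs in records_by_arm.values() for rec in recs}
    if len(fs_vals) != 1:
        raise ValueError("mismatched sampling rates between arms")
    rows = []
    per_arm_band: dict[str, dict[str, list[float]]] = {}
    for arm, recs in records_by_arm.items():
        per_arm_band[arm] = {b: [] for b in BAND_NAMES}
        for rec in recs:
            x = rec.channel(channel)
            for b in BAND_NAMES:
                per_arm_band[arm][b].append(
                    welch_band_power(x, BANDS[b], rec.fs))
        for b in BAND_NAMES:
            rows.append({"arm": arm, "band": b,
                         "mean_power_mV2": float(np.mean(per_arm_band[arm][b])),
                         "n_records": len(recs)})
    df = pd.DataFrame(rows)
    pvals = {}
    if all(len(v[BAND_NAMES[0]]) >= 2 for v in per_arm_band.values()):
        for b in BAND_NAMES:
            groups = [per_arm_band[a][b] for a in records_by_arm]
            pvals[b] = float(stats.kruskal(*groups).pvalue)
    df.attrs["kruskal_p"] = pvals
    return df


def _hash_config(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:12]


def render_report(bundle: AnalysisBundle, out_dir) -> Path:
    """Render a Markdown report plus CSV tables; deterministic per bundle.

    Missing components are listed in the manifest and the report still
    renders. Returns the path to the Markdown file.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines = ["# SNF stimulation simulation report", ""]
    manifest = {
        "missing": bundle.missing(),
        "provenance": bundle.provenance,
        "config_hash": _hash_config(bundle.provenance),
    }
    lines += ["## Manifest", "```json",
              json.dumps(manifest, indent=1, sort_keys=True), "```", ""]

    if bundle.detection is not None:
        lines += ["## Detection", ""]
        for k, v in sorted(bundle.detection.items()):
            lines.append(f"- {k}: {v}")
        lines.append("")
    if bundle.synchrony is not None:
        lines += ["## Synchrony", ""]
        for k, v in sorted(bundle.synchrony.items()):
            lines.append(f"- {k}: {v}")
        lines.append("")
    if bundle.field_summary is not None:
        lines += ["## Field model", ""]
        for k, v in sorted(bundle.field_summary.items()):
            lines.append(f"- {k}: {v}")
        lines.append("")
    if bundle.thresholds is not None:
        bundle.thresholds.to_csv(out / "thresholds.csv", index=False)
        lines += ["## Activation thresholds",
                  "", "See `thresholds.csv`.",
                  bundle.thresholds.describe().to_markdown(), ""]
    if bundle.endpoints is not None:
        bundle.endpoints.to_csv(out / "endpoints.csv", index=False)
        lines += ["## Closed-loop endpoints", "",
                  bundle.endpoints.to_markdown(index=False), ""]
    md = out / "report.md"
    md.write_text("\n".join(lines))
    return md


def endpoints_table(endpoint_sets: dict) -> pd.DataFrame:
    """Flatten per-arm SessionEndpoints into one tidy frame."""
    rows = []
    for arm, eps in endpoint_sets.items():
        for i, ep in enumerate(eps):
            rows.append({
                "arm": arm, "session": i,
                "pct_time_in_seizure": ep.pct_time_in_seizure,
                "success_rate": ep.termination_success_rate,
                "median_latency_s": ep.median_latency,
                "n_events": ep.n_events,
            })
    return pd.DataFrame(rows)
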