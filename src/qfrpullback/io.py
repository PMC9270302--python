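"""Trace files and cohort manifests.

A trace file is a UTF-8 TSV with header ``position_mm<TAB>qfr`` and one row
per sample ('.' decimal separator); vessel id and phase travel in the
manifest or the filename.  The cohort manifest is JSON: an echo of the
generating spec plus one record per vessel with the trace file paths,
ground-truth pattern and simulated outcome.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .errors import TraceParseError
from .simulate import CohortSpec, SyntheticVessel
from .trace import PRE_PCI, PullbackTrace

_HEADER = "position_mm\tqfr"


def read_trace(path: str | Path, vessel_id: str | None = None, phase: str = PRE_PCI) -> PullbackTrace:
    """Read a trace TSV; malformed rows are reported with their line number."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise TraceParseError("no samples: file is empty")
    start = 1 if "position" in lines[0].lower() else 0
    positions, qfr = [], []
    prev = -np.inf
    for ln, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise TraceParseError(f"expected 2 tab-separated columns, got {len(parts)}", ln)
        try:
            p, q = float(parts[0]), float(parts[1])
        except ValueError:
            raise TraceParseError(f"non-numeric cell in {parts!r}", ln) from None
        if p <= prev:
            raise TraceParseError(
                f"positions must be strictly increasing ({p} after {prev})", ln
            )
        prev = p
        positions.append(p)
        qfr.append(q)
    if not positions:
        raise TraceParseError("no samples: file contains no data rows")
    return PullbackTrace(
        vessel_id=vessel_id or path.stem,
        positions_mm=np.asarray(positions),
        qfr=np.asarray(qfr),
        phase=phase,
    )


def write_trace(trace: PullbackTrace, path: str | Path) -> None:
    """Write a trace TSV (6 decimal places, lossless round-trip at 1e-6)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(_HEADER + "\n")
        for p, q in zip(trace.positions_mm, trace.qfr):
            fh.write(f"{p:.6f}\t{q:.6f}\n")


def write_manifest(
    cohort: list[SyntheticVessel], spec: CohortSpec, out_dir: str | Path
) -> Path:
    """Write all trace files plus the cohort manifest JSON; returns its path."""
    out_dir = Path(out_dir)
    traces_dir = out_dir / "traces"
    traces_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for v in cohort:
        pre_path = traces_dir / f"{v.vessel_id}_pre.tsv"
        write_trace(v.trace_pre, pre_path)
        rec = {
            "patient_id": v.patient_id,
            "vessel_id": v.vessel_id,
            "true_pattern": v.true_pattern,
            "pre_trace": str(pre_path.relative_to(out_dir)),
            "post_trace": None,
            "post_qfr": v.post_qfr,
            "stented_intervals": [list(map(float, s)) for s in v.stented_intervals],
        }
        if v.trace_post is not None:
            post_path = traces_dir / f"{v.vessel_id}_post.tsv"
            write_trace(v.trace_post, post_path)
            rec["post_trace"] = str(post_path.relative_to(out_dir))
        records.append(rec)
    spec_dict = dataclasses.asdict(spec)
    spec_dict["tvl_range_mm"] = list(spec.tvl_range_mm)
    spec_dict["distal_qfr_range"] = list(spec.distal_qfr_range)
    manifest = {"spec": spec_dict, "vessels": records}
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest_path


def read_manifest(manifest_path: str | Path) -> tuple[CohortSpec, list[SyntheticVessel]]:
    """Load a cohort back from a manifest; trace files are re-read from disk.

    Missing trace files raise :class:`FileNotFoundError` naming the vessel.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    data = json.loads(manifest_path.read_text(encoding="utf-8"))
    sd = dict(data["spec"])
    sd["tvl_range_mm"] = tuple(sd["tvl_range_mm"])
    sd["distal_qfr_range"] = tuple(sd["distal_qfr_range"])
    spec = CohortSpec(**sd)
    vessels = []
    for rec in data["vessels"]:
        pre_file = base / rec["pre_trace"]
        if not pre_file.exists():
            raise FileNotFoundError(
                f"vessel {rec['vessel_id']}: trace file {pre_file} not found"
            )
        trace_pre = read_trace(pre_file, vessel_id=rec["vessel_id"], phase="pre_pci")
        trace_post = None
        if rec.get("post_trace"):
            post_file = base / rec["post_trace"]
            if not post_file.exists():
                raise FileNotFoundError(
                    f"vessel {rec['vessel_id']}: trace file {post_file} not found"
                )
            trace_post = read_trace(post_file, vessel_id=rec["vessel_id"], phase="post_pci")
        vessels.append(
            SyntheticVessel(
                vessel_id=rec["vessel_id"],
                patient_id=rec["patient_id"],
                true_pattern=rec["true_pattern"],
                ostial_qfr=trace_pre.ostial_qfr,
                tvl_mm=trace_pre.tvl_mm,
                components=[],
                trace_pre=trace_pre,
                trace_post=trace_post,
                post_qfr=rec.get("post_qfr"),
                stented_intervals=[tuple(s) for s in rec.get("stented_intervals", [])],
            )
        )
    return spec, vessels
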