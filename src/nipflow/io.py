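"""Format plumbing: trace CSV + JSON sidecars, aligned FASTA, reports.

Traces are stored one per file with header ``time_s,signal`` and a sidecar
``<name>.meta.json`` carrying shock metadata; strain cohorts are described by
a manifest CSV (``strain,file,temperature_C,shock_kind``).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .kinetics import ShockConditions, ShockTrace

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "write_report_json",
    "read_fasta_alignment",
    "write_fasta_alignment",
    "write_profile_tsv",
]


def write_trace_csv(trace: ShockTrace, path) -> None:
    path = Path(path)
    pd.DataFrame({"time_s": trace.time, "signal": trace.signal}).to_csv(
        path, index=False, float_format="%.10g"
    )
    meta = {
        "temperature_C": trace.temperature,
        "shock_kind": trace.shock_kind,
        "osm_in_osmolar": trace.conditions.osm_in_initial,
        "osm_out_osmolar": trace.conditions.osm_out_final,
        "shock_solute": trace.conditions.shock_solute,
        "signal_baseline": trace.signal_baseline,
        "signal_span": trace.signal_span,
        "strain": trace.strain,
        "seed": trace.meta.get("seed"),
        "mode": trace.meta.get("mode"),
    }
    sidecar = path.with_suffix(".meta.json")
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def read_trace_csv(path) -> ShockTrace:
    path = Path(path)
    frame = pd.read_csv(path)
    if not {"time_s", "signal"} <= set(frame.columns):
        raise InvalidParameterError(f"{path}: expected columns time_s,signal")
    sidecar = path.with_suffix(".meta.json")
    if not sidecar.exists():
        raise InvalidParameterError(f"missing sidecar metadata {sidecar}")
    meta = json.loads(sidecar.read_text())
    conditions = ShockConditions(
        osm_in_initial=meta["osm_in_osmolar"],
        osm_out_final=meta["osm_out_osmolar"],
        shock_solute=meta.get("shock_solute", "sorbitol"),
    )
    return ShockTrace(
        time=np.asarray(frame["time_s"], dtype=float),
        signal=np.asarray(frame["signal"], dtype=float),
        temperature=meta["temperature_C"],
        shock_kind=meta["shock_kind"],
        conditions=conditions,
        signal_baseline=meta.get("signal_baseline", 0.0),
        signal_span=meta.get("signal_span", 1.0),
        strain=meta.get("strain"),
        meta={"seed": meta.get("seed"), "mode": meta.get("mode")},
    )


def write_report_json(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def read_fasta_alignment(path) -> dict[str, str]:
    from Bio import SeqIO

    records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise InvalidParameterError(f"{path}: no FASTA records")
    lengths = {len(s) for s in records.values()}
    if len(lengths) != 1:
        raise InvalidParameterError(f"{path}: sequences not aligned (unequal lengths)")
    return records


def write_fasta_alignment(sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def write_profile_tsv(profile, path) -> None:
    pd.DataFrame(
        {
            "z_A": profile.z,
            "radius_A": profile.radius,
            "cx": profile.center_xy[:, 0],
            "cy": profile.center_xy[:, 1],
            "blocked": profile.blocked.astype(int),
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")
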