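"""Tabular readers/writers and provenance for the pipeline's file formats.

All tables are UTF-8, tab-separated, ``.`` decimal separator, scientific
notation permitted. Writers can prepend a provenance block as ``#``-prefixed
comment lines (tool version, config hash, seed, input digests); readers skip
such lines. Identical inputs and config produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from . import __version__
from .calling import LODEntry, MRDCall, SampleQC
from .config import RunConfig, config_hash
from .quantify import ReplicateCount

__all__ = [
    "provenance_lines", "file_digest", "write_counts_tsv", "read_counts_tsv",
    "write_lod_tsv", "read_lod_tsv", "read_metadata_tsv", "read_mfc_tsv",
    "write_calls", "read_calls_json", "JsonLinesLogger",
]

PathLike = Union[str, Path]


def file_digest(path: PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:12]


def provenance_lines(cfg: Optional[RunConfig] = None,
                     inputs: Sequence[PathLike] = ()) -> list[str]:
    lines = [f"# liqbio {__version__}"]
    if cfg is not None:
        lines.append(f"# config_hash {config_hash(cfg)} seed {cfg.seed}")
    for p in inputs:
        lines.append(f"# input {Path(p).name} sha256:{file_digest(p)}")
    return lines


def _write_table(df: pd.DataFrame, path: PathLike,
                 prov: Optional[list[str]] = None) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in prov or []:
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def _read_table(path: PathLike, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# ---------------------------------------------------------------------------
# counts

def write_counts_tsv(counts: Iterable[ReplicateCount], path: PathLike,
                     prov: Optional[list[str]] = None) -> None:
    rows = [{
        "marker_id": c.marker_id, "replicate": c.replicate,
        "n_wt": c.n_wt, "n_mut": c.n_mut,
        "n_unclassified": c.n_unclassified,
        "vaf": "" if c.vaf is None else repr(c.vaf),
    } for c in counts]
    df = pd.DataFrame(rows, columns=["marker_id", "replicate", "n_wt",
                                     "n_mut", "n_unclassified", "vaf"])
    _write_table(df, path, prov)


def read_counts_tsv(path: PathLike) -> list[ReplicateCount]:
    df = _read_table(path, dtype={"marker_id": str})
    return [ReplicateCount(
        marker_id=row.marker_id, replicate=int(row.replicate),
        n_wt=int(row.n_wt), n_mut=int(row.n_mut),
        n_unclassified=int(row.n_unclassified),
    ) for row in df.itertuples()]


def group_counts_by_marker(
        counts: Iterable[ReplicateCount]) -> dict[str, list[ReplicateCount]]:
    grouped: dict[str, list[ReplicateCount]] = {}
    for c in counts:
        grouped.setdefault(c.marker_id, []).append(c)
    return grouped


# ---------------------------------------------------------------------------
# LOD

def write_lod_tsv(entries: Iterable[LODEntry], path: PathLike,
                  prov: Optional[list[str]] = None) -> None:
    df = pd.DataFrame([{
        "marker_id": e.marker_id, "lod": repr(e.lod),
        "mean": repr(e.mean), "n_points": len(e.control_vafs),
        "control_vafs": ",".join(repr(v) for v in e.control_vafs),
    } for e in entries])
    _write_table(df, path, prov)


def read_lod_tsv(path: PathLike) -> dict[str, LODEntry]:
    df = _read_table(path, dtype={"marker_id": str, "control_vafs": str})
    out = {}
    for row in df.itertuples():
        vafs = tuple(float(v) for v in str(row.control_vafs).split(","))
        out[row.marker_id] = LODEntry(marker_id=row.marker_id,
                                      control_vafs=vafs, lod=float(row.lod))
    return out


# ---------------------------------------------------------------------------
# metadata / MFC

def read_metadata_tsv(path: PathLike) -> list[SampleQC]:
    df = _read_table(path, dtype={"sample_id": str, "fraction": str})
    out = []
    for row in df.itertuples():
        ratio = getattr(row, "gdna_cfdna_ratio", None)
        if ratio is not None and pd.isna(ratio):
            ratio = None
        out.append(SampleQC(sample_id=row.sample_id, fraction=row.fraction,
                            dna_ng=float(row.dna_ng),
                            gdna_cfdna_ratio=None if ratio is None
                            else float(ratio)))
    return out


def read_mfc_tsv(path: PathLike) -> dict[str, bool]:
    df = _read_table(path, dtype={"sample_id": str})
    return {row.sample_id: bool(row.mfc_positive)
            for row in df.itertuples()}


# ---------------------------------------------------------------------------
# calls

def _call_to_dict(call: MRDCall) -> dict:
    return {
        "sample_id": call.sample_id, "fraction": call.fraction,
        "best_marker": call.best_marker, "mrd_value": call.mrd_value,
        "positive": call.positive, "threshold": call.threshold,
        "warnings": list(call.warnings),
        "markers": [{
            "marker_id": m.marker_id, "status": m.status,
            "marker_vaf": m.marker_vaf, "lod": m.lod,
            "retained_replicates": list(m.retained_replicates),
            "replicate_vafs": {c.replicate: c.vaf
                               for c in m.replicate_counts},
        } for m in call.provenance],
    }


def write_calls(calls: Sequence[MRDCall], json_path: PathLike,
                tsv_path: Optional[PathLike] = None,
                cfg: Optional[RunConfig] = None,
                prov: Optional[list[str]] = None) -> None:
    payload = {
        "tool": "liqbio", "version": __version__,
        "config": cfg.to_dict() if cfg else None,
        "calls": [_call_to_dict(c) for c in calls],
    }
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")
    if tsv_path is not None:
        df = pd.DataFrame([{
            "sample_id": c.sample_id, "fraction": c.fraction,
            "mrd_value": repr(c.mrd_value), "positive": c.positive,
            "best_marker": c.best_marker or "",
        } for c in calls])
        _write_table(df, tsv_path, prov)


def read_calls_json(path: PathLike) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


class JsonLinesLogger:
    """Machine log: one JSON object per line, counts at every filter."""

    def __init__(self, path: Optional[PathLike] = None, echo: bool = False):
        self.path = Path(path) if path else None
        self.echo = echo
        self._fh = open(self.path, "a", encoding="utf-8") if self.path else None

    def log(self, event: str, **fields) -> None:
        record = {"event": event, **fields}
        if self._fh:
            self._fh.write(json.dumps(record, sort_keys=True) + "\n")
            self._fh.flush()
        if self.echo:
            print(f"[liqbio] {event}: " +
                  " ".join(f"{k}={v}" for k, v in fields.items()),
                  file=sys.stderr)

    def close(self) -> None:
        if self._fh:
            self._fh.close()
            self._fh = None

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()
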