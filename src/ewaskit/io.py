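"""Readers and writers for the plain-text formats the pipeline exchanges.

Conventions
-----------
* Beta and detection-p matrices: tab-separated, probes as rows, first
  column the probe ID, header row the sample IDs.
* Sample sheets: CSV keyed by ``sample_id``.
* Probe annotation: BED-like tab-separated table with 0-based half-open
  coordinates and columns ``chrom, start, end, probe_id, design_class,
  context, snp_overlap, cross_reactive, promoter_id, gene_id``.
* Gene sets: standard GMT (set name, description, tab-separated members).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from gseapy.parser import read_gmt as _gseapy_read_gmt

ANNOTATION_COLUMNS = [
    "chrom",
    "start",
    "end",
    "probe_id",
    "design_class",
    "context",
    "snp_overlap",
    "cross_reactive",
    "promoter_id",
    "gene_id",
]

#: float format used for every numeric table so reruns are byte-identical
FLOAT_FORMAT = "%.10g"


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "probe_id") -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label=index_label)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, index_label="sample_id", float_format=FLOAT_FORMAT)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="sample_id")


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    """Write probe annotation as a BED-like table (0-based half-open)."""
    out = annotation.reset_index().rename(columns={"index": "probe_id"})
    out = out[ANNOTATION_COLUMNS]
    out.to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    ann = ann.set_index("probe_id")
    for col in ("snp_overlap", "cross_reactive"):
        ann[col] = ann[col].astype(bool)
    return ann


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT gene-set collection into ``{set_name: [genes...]}``."""
    return _gseapy_read_gmt(str(path))


def write_gmt(
    gene_sets: Mapping[str, Sequence[str]],
    path: str | Path,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if hasattr(obj, "tolist"):
        return obj.tolist()
    if hasattr(obj, "item"):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)!r}")
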