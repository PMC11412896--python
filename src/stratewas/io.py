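"""Readers and writers for the pipeline's tabular formats.

Conventions: TSV for matrices and summary statistics, CSV for sample
sheets, JSON for parameter sidecars, BED (0-based half-open) for
genome-browser exports.  All genomic coordinates are 1-based inclusive in
memory and in the native TSVs; only the BED writer converts.  P-values are
serialized in scientific notation with six significant digits.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .bacon import BaconParams
from .containers import BetaMatrix
from .exceptions import ParseError, SchemaError

__all__ = [
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_sumstats",
    "write_sumstats",
    "read_meta",
    "write_meta",
    "write_dmr_table",
    "write_dmr_bed",
    "write_bacon_params",
    "read_bacon_params",
]

_PFMT = "%.5E"  # six significant digits
_P_COLS = {"p", "p_bc", "p_fe", "p_re", "p_region", "p_sidak"}


def _fmt(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for c in out.columns:
        if c in _P_COLS:
            out[c] = out[c].map(lambda v: _PFMT % v if pd.notna(v) else "NA")
    return out


# ---------------------------------------------------------------------------
# beta matrix + annotation
# ---------------------------------------------------------------------------

def write_beta_matrix(bm: BetaMatrix, values_path, annot_path) -> None:
    vals = bm.values.copy()
    vals.index.name = "probe"
    vals.to_csv(values_path, sep="\t")
    annot = bm.annot.copy()
    annot.index.name = "probe"
    annot.to_csv(annot_path, sep="\t")


def read_beta_matrix(values_path, annot_path) -> BetaMatrix:
    values_path, annot_path = Path(values_path), Path(annot_path)
    try:
        vals = pd.read_csv(values_path, sep="\t", index_col=0)
    except Exception as exc:
        raise ParseError(f"{values_path}: malformed matrix header or body ({exc})") from exc
    if vals.index.has_duplicates:
        dup = vals.index[vals.index.duplicated()][0]
        line = int(np.where(vals.index == dup)[0][-1]) + 2
        raise ParseError(f"{values_path}: duplicate probe id {dup!r} at line {line}")
    arr = vals.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ParseError(f"{values_path}: non-numeric beta values")
    bad = np.argwhere((arr < 0) | (arr > 1))
    if bad.size:
        r, c = bad[0]
        raise ParseError(
            f"{values_path}: beta value {arr[r, c]} out of [0, 1] at line {r + 2}, "
            f"column {vals.columns[c]!r}"
        )
    annot = pd.read_csv(annot_path, sep="\t", index_col=0)
    need = {"chrom", "pos"}
    if not need.issubset(annot.columns):
        raise SchemaError(f"{annot_path}: missing columns {sorted(need - set(annot.columns))}")
    missing = vals.index.difference(annot.index)
    if len(missing):
        raise ParseError(
            f"{annot_path}: probes missing annotation: " + ", ".join(map(str, missing[:5]))
        )
    return BetaMatrix(vals, annot)


# ---------------------------------------------------------------------------
# sample sheets and summary statistics
# ---------------------------------------------------------------------------

def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path)
    if "sample_id" not in sheet.columns:
        raise SchemaError(f"{path}: sample sheet must have a sample_id column")
    return sheet


_SUMSTAT_REQUIRED = ["probe", "effect", "se", "p"]


def write_sumstats(table: pd.DataFrame, path) -> None:
    _fmt(table).to_csv(path, sep="\t", index=False)


def read_sumstats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _SUMSTAT_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: summary statistics missing columns {missing}")
    return df


_META_REQUIRED = ["probe", "k", "effect_fe", "se_fe", "p_fe", "effect_re", "se_re", "p_re"]


def write_meta(table: pd.DataFrame, path) -> None:
    _fmt(table).to_csv(path, sep="\t", index=False)


def read_meta(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _META_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: meta table missing columns {missing}")
    return df


# ---------------------------------------------------------------------------
# DMR outputs
# ---------------------------------------------------------------------------

def write_dmr_table(table: pd.DataFrame, path) -> None:
    """Native region table: CHR, Start BP, End BP, Probes, P-value, Sidak P-value."""
    out = pd.DataFrame(
        {
            "CHR": table["chrom"],
            "Start BP": table["start_bp"],
            "End BP": table["end_bp"],
            "Probes": table["n_probes"],
            "P-value": table["p_region"].map(lambda v: _PFMT % v),
            "Sidak P-value": table["p_sidak"].map(lambda v: _PFMT % v),
            "Probe IDs": table.get("probe_ids", ""),
        }
    )
    out.to_csv(path, sep="\t", index=False)


def write_dmr_bed(table: pd.DataFrame, path) -> None:
    """BED6+ export; converts 1-based inclusive to 0-based half-open."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\tp_region\tp_sidak\n")
        for i, row in table.reset_index(drop=True).iterrows():
            fh.write(
                "\t".join(
                    [
                        str(row["chrom"]),
                        str(int(row["start_bp"]) - 1),
                        str(int(row["end_bp"])),
                        f"DMR{i + 1}",
                        "0",
                        ".",
                        _PFMT % row["p_region"],
                        _PFMT % row["p_sidak"],
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# parameter sidecars
# ---------------------------------------------------------------------------

def write_bacon_params(params: BaconParams, path) -> None:
    with open(path, "w") as fh:
        json.dump(params.to_dict(), fh, indent=2)


def read_bacon_params(path) -> BaconParams:
    with open(path) as fh:
        return BaconParams.from_dict(json.load(fh))
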