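"""Readers and writers for the tabular formats the pipeline touches.

Coordinate conventions
----------------------
SEG tables (segmented copy number) use **1-based inclusive** genomic
coordinates, the GDC convention. BEDPE uses **0-based half-open**
intervals; when a single breakpoint coordinate is needed, the interval
*start* is used. Converters between the two conventions are provided
(:func:`to_zero_based`, :func:`to_one_based`).

Chromosome names are normalized on read by stripping any ``chr`` prefix,
since TCGA- and PCAWG-style exports differ. Unknown extra columns are
preserved but ignored. All writers emit tab-separated UTF-8 with a
single header line.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "SEG_COLUMNS",
    "BEDPE_COLUMNS",
    "MUTATION_COLUMNS",
    "CLINICAL_COLUMNS",
    "SV_TYPES",
    "SILENT_CLASS",
    "normalize_chromosome",
    "chromosome_sort_key",
    "read_seg",
    "write_seg",
    "read_bedpe",
    "write_bedpe",
    "read_mutations",
    "write_mutations",
    "filter_silent",
    "read_counts",
    "write_counts",
    "read_clinical",
    "write_clinical",
    "read_gmt",
    "write_gmt",
    "to_zero_based",
    "to_one_based",
]


class FormatError(ValueError):
    """Raised for malformed or invariant-violating input files."""


SEG_COLUMNS = ["sample_id", "chromosome", "start", "end", "num_probes", "segment_mean"]
BEDPE_CORE = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
BEDPE_COLUMNS = BEDPE_CORE + ["name", "score", "strand1", "strand2"]
MUTATION_COLUMNS = ["sample_id", "gene", "chromosome", "position", "variant_classification"]
CLINICAL_COLUMNS = [
    "sample_id", "cancer_type", "age", "sex", "stage", "msi_status",
    "treated", "os_time", "os_event", "dfs_time", "dfs_event",
]

SV_TYPES = frozenset({"DEL", "DUP", "INS", "INV", "TRA"})
#: SV classes that change copy number and therefore must be intra-chromosomal.
INTRACHROMOSOMAL_TYPES = frozenset({"DEL", "DUP", "INS", "INV"})
SILENT_CLASS = "Silent"

STAGES = ("I", "II", "III", "IV", "NA")
MSI_STATES = ("MSS", "MSI", "NA")

# lowercase header -> canonical name, covering classic SEG / MAF dialects
_SEG_ALIASES = {
    "id": "sample_id", "sample": "sample_id", "sample_id": "sample_id",
    "chrom": "chromosome", "chromosome": "chromosome",
    "loc.start": "start", "start": "start",
    "loc.end": "end", "end": "end",
    "num.mark": "num_probes", "num_probes": "num_probes", "num.probes": "num_probes",
    "seg.mean": "segment_mean", "segment_mean": "segment_mean",
}
_MAF_ALIASES = {
    "tumor_sample_barcode": "sample_id", "sample_id": "sample_id",
    "hugo_symbol": "gene", "gene": "gene",
    "chromosome": "chromosome",
    "start_position": "position", "position": "position",
    "variant_classification": "variant_classification",
}


def normalize_chromosome(chrom) -> str:
    """Canonical chromosome label: string, without any ``chr`` prefix."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c


def chromosome_sort_key(chrom: str) -> tuple:
    """Natural ordering: 1..22, X, Y, MT, then anything else lexicographically."""
    c = normalize_chromosome(chrom)
    if c.isdigit():
        return (0, int(c), "")
    special = {"X": 23, "Y": 24, "M": 25, "MT": 25}
    if c.upper() in special:
        return (0, special[c.upper()], "")
    return (1, 0, c)


def to_zero_based(start_1based: int) -> int:
    """1-based inclusive start -> 0-based half-open start."""
    return int(start_1based) - 1


def to_one_based(start_0based: int) -> int:
    """0-based half-open start -> 1-based inclusive start."""
    return int(start_0based) + 1


def _rename_aliases(df: pd.DataFrame, aliases: Mapping[str, str]) -> pd.DataFrame:
    return df.rename(columns={c: aliases.get(c.lower(), c) for c in df.columns})


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing required column(s): {', '.join(missing)}")


def _to_numeric(df: pd.DataFrame, col: str, what: str, integer: bool = False) -> pd.Series:
    """Strict numeric conversion; reports the 1-based file line of the first bad value."""
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # +1 header, +1 1-based
        raise FormatError(f"{what}: non-numeric value in column '{col}' at line {line}")
    return vals.astype(np.int64) if integer else vals.astype(float)


def sort_seg(df: pd.DataFrame) -> pd.DataFrame:
    key = df["chromosome"].map(chromosome_sort_key)
    return (
        df.assign(_ck=key)
        .sort_values(["sample_id", "_ck", "start"], kind="stable")
        .drop(columns="_ck")
        .reset_index(drop=True)
    )


def validate_seg(df: pd.DataFrame, what: str = "SEG data") -> None:
    """Check segment invariants: coordinates, probe counts, non-overlap."""
    if (df["start"] > df["end"]).any():
        raise FormatError(f"{what}: segment with start > end")
    if (df["num_probes"] < 1).any():
        raise FormatError(f"{what}: segment with num_probes < 1")
    for (sample, chrom), grp in df.groupby(["sample_id", "chromosome"], sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        order = np.argsort(starts, kind="stable")
        if np.any(starts[order][1:] <= ends[order][:-1]):
            raise FormatError(
                f"{what}: overlapping segments for sample {sample} chromosome {chrom}"
            )


def read_seg(path) -> pd.DataFrame:
    """Read a SEG file (1-based inclusive) into a sorted, validated frame.

    Records are sorted by sample, chromosome (natural order) and start.
    Overlapping segments within one sample+chromosome raise
    :class:`FormatError`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    df = _rename_aliases(df, _SEG_ALIASES)
    _require_columns(df, SEG_COLUMNS, f"SEG file {path}")
    out = df.copy()
    out["sample_id"] = out["sample_id"].astype(str)
    out["chromosome"] = out["chromosome"].map(normalize_chromosome)
    for col in ("start", "end", "num_probes"):
        out[col] = _to_numeric(df, col, f"SEG file {path}", integer=True)
    out["segment_mean"] = _to_numeric(df, "segment_mean", f"SEG file {path}")
    out = sort_seg(out)
    validate_seg(out, f"SEG file {path}")
    return out


def write_seg(df: pd.DataFrame, path) -> None:
    _require_columns(df, SEG_COLUMNS, "SEG frame")
    cols = SEG_COLUMNS + [c for c in df.columns if c not in SEG_COLUMNS]
    df[cols].to_csv(path, sep="\t", index=False)


def read_bedpe(
    path,
    sv_type_col: str = "sv_type",
    filter_col: str = "filter_pass",
    sample_col: str = "sample_id",
    require_pass: bool = True,
) -> pd.DataFrame:
    """Read SV calls from BEDPE (0-based half-open).

    The columns carrying the SV type, filter status, and sample identity
    are configurable because portal exports differ. When ``require_pass``
    is set and a filter column is present, only passing records are
    retained.
    """
    df = pd.read_csv(path, sep="\t", dtype={sample_col: str})
    _require_columns(df, BEDPE_CORE + [sv_type_col, sample_col], f"BEDPE file {path}")
    out = df.rename(columns={sv_type_col: "sv_type", sample_col: "sample_id"})
    if filter_col in out.columns and filter_col != "filter_pass":
        out = out.rename(columns={filter_col: "filter_pass"})
    out["chrom1"] = out["chrom1"].map(normalize_chromosome)
    out["chrom2"] = out["chrom2"].map(normalize_chromosome)
    out["sv_type"] = out["sv_type"].astype(str).str.upper()
    unknown = sorted(set(out["sv_type"]) - SV_TYPES)
    if unknown:
        raise FormatError(f"BEDPE file {path}: unknown sv_type value(s): {', '.join(unknown)}")
    if "filter_pass" in out.columns:
        out["filter_pass"] = out["filter_pass"].map(_as_bool).astype(bool)
        if require_pass:
            out = out.loc[out["filter_pass"]].reset_index(drop=True)
    else:
        out["filter_pass"] = True
    intra = out["sv_type"].isin(INTRACHROMOSOMAL_TYPES)
    cross = intra & (out["chrom1"] != out["chrom2"])
    if cross.any():
        bad = out.loc[cross, "sv_type"].iloc[0]
        raise FormatError(
            f"BEDPE file {path}: intra-chromosomal sv_type {bad} on an "
            "inter-chromosomal breakpoint pair"
        )
    if (intra & (out["start1"] > out["start2"])).any():
        raise FormatError(f"BEDPE file {path}: intra-chromosomal record with pos1 > pos2")
    return out.reset_index(drop=True)


def _as_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    return str(v).strip().upper() in {"TRUE", "PASS", "1", "YES", "T"}


def write_bedpe(df: pd.DataFrame, path) -> None:
    _require_columns(df, BEDPE_CORE + ["sv_type", "sample_id"], "BEDPE frame")
    first = ["sample_id"] + BEDPE_CORE + ["sv_type", "filter_pass"]
    cols = [c for c in first if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, sep="\t", index=False)


def read_mutations(path, dedup: bool = False) -> pd.DataFrame:
    """Read a MAF-like mutation table.

    All records are returned; removal of silent variants is a downstream
    option (:func:`filter_silent`), applied by default in the genome-wide
    association screen. Records lacking a gene symbol are skipped with a
    logged warning; the skip count is stored in ``df.attrs['n_skipped']``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    df = _rename_aliases(df, _MAF_ALIASES)
    _require_columns(df, MUTATION_COLUMNS, f"mutation file {path}")
    missing_gene = df["gene"].isna() | (df["gene"].astype(str).str.strip() == "")
    n_skipped = int(missing_gene.sum())
    if n_skipped:
        logger.warning("mutation file %s: skipped %d record(s) without gene symbol", path, n_skipped)
    out = df[~missing_gene].copy()
    out["chromosome"] = out["chromosome"].map(normalize_chromosome)
    out["position"] = _to_numeric(out.reset_index(drop=True), "position",
                                  f"mutation file {path}", integer=True).to_numpy()
    if dedup:
        out = out.drop_duplicates(subset=MUTATION_COLUMNS)
    out = out.reset_index(drop=True)
    out.attrs["n_skipped"] = n_skipped
    return out


def write_mutations(df: pd.DataFrame, path) -> None:
    _require_columns(df, MUTATION_COLUMNS, "mutation frame")
    cols = MUTATION_COLUMNS + [c for c in df.columns if c not in MUTATION_COLUMNS]
    df[cols].to_csv(path, sep="\t", index=False)


def filter_silent(df: pd.DataFrame) -> pd.DataFrame:
    """Drop variants whose classification is Silent (non-coding for the screen)."""
    return df[df["variant_classification"] != SILENT_CLASS].reset_index(drop=True)


def read_counts(path) -> pd.DataFrame:
    """Read a gene-by-sample raw count matrix (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise FormatError(f"counts file {path}: non-numeric entries")
    if np.any(arr < 0) or np.any(arr != np.floor(arr)):
        raise FormatError(f"counts file {path}: counts must be non-negative integers")
    df.index.name = "gene"
    return df.astype(np.int64)


def write_counts(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, CLINICAL_COLUMNS, f"clinical file {path}")
    out = df.copy()
    out["age"] = _to_numeric(df, "age", f"clinical file {path}")
    for col in ("os_time", "dfs_time"):
        out[col] = _to_numeric(df, col, f"clinical file {path}")
        if (out[col] < 0).any():
            raise FormatError(f"clinical file {path}: negative {col}")
    for col in ("os_event", "dfs_event"):
        out[col] = _to_numeric(df, col, f"clinical file {path}", integer=True)
        if not out[col].isin((0, 1)).all():
            raise FormatError(f"clinical file {path}: {col} must be 0/1")
    out["treated"] = out["treated"].map(_as_bool)
    bad_stage = set(out["stage"]) - set(STAGES)
    if bad_stage:
        raise FormatError(f"clinical file {path}: unknown stage value(s): {sorted(bad_stage)}")
    bad_msi = set(out["msi_status"]) - set(MSI_STATES)
    if bad_msi:
        raise FormatError(f"clinical file {path}: unknown msi_status value(s): {sorted(bad_msi)}")
    return out.reset_index(drop=True)


def write_clinical(df: pd.DataFrame, path) -> None:
    _require_columns(df, CLINICAL_COLUMNS, "clinical frame")
    cols = CLINICAL_COLUMNS + [c for c in df.columns if c not in CLINICAL_COLUMNS]
    df[cols].to_csv(path, sep="\t", index=False)


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets from GMT: name, description, then member genes."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")
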