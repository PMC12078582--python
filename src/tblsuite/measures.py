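"""Per-sample genomic-instability measures: TBL, FGA and TMB.

The tumor break load (TBL) counts unbalanced somatic chromosomal
breaks. From segmented copy-number data a candidate break is the
boundary between two adjacent segments of the same chromosome; a break
is retained when its smallest adjacent segment size (SAS, in probes)
and its break size (BrS, the absolute change in segment mean) both
reach their thresholds and the boundary is not seen in the normal
panel. Removal is ``SAS < 20 OR BrS < 0.135`` (strict below), so a
break sitting exactly at a threshold is retained. From SV calls the
TBL sums breakpoints of copy-number-changing events (DEL, DUP).

FGA is the fraction of profiled genome length in segments whose
|log2 ratio| reaches a threshold (default 0.2); TMB counts non-silent
small variants, optionally per megabase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io_formats

logger = logging.getLogger(__name__)

__all__ = [
    "BreakFilterParams",
    "BREAK_STATUSES",
    "build_normal_blacklist",
    "call_breaks",
    "tbl_from_segments",
    "tbl_from_sv",
    "compute_fga",
    "compute_tmb",
    "compute_measure_table",
]

UNBALANCED_SV_TYPES = frozenset({"DEL", "DUP"})
BREAK_STATUSES = ("retained", "filtered_sas", "filtered_brs", "filtered_normal")


@dataclass(frozen=True)
class BreakFilterParams:
    """Retention thresholds for candidate chromosomal breaks.

    ``sas_min`` is in probes, ``brs_min`` in segment-mean (log2 ratio)
    units, ``normal_match_tolerance`` in bp around blacklisted
    boundaries (0 = exact-coordinate matching).
    """

    sas_min: int = 20
    brs_min: float = 0.135
    normal_match_tolerance: int = 0

    def __post_init__(self) -> None:
        if self.sas_min < 1:
            raise ValueError("sas_min must be >= 1")
        if self.brs_min < 0 or self.normal_match_tolerance < 0:
            raise ValueError("brs_min and normal_match_tolerance must be >= 0")


def build_normal_blacklist(normal_seg: pd.DataFrame,
                           params: BreakFilterParams | None = None) -> set[tuple[str, int]]:
    """Union of all segment boundaries observed in any normal sample.

    No SAS/BrS filtering is applied to the normals: any break present in
    a normal is treated as germline or a platform artifact. An empty
    panel yields an empty blacklist with a warning.
    """
    if normal_seg is None or len(normal_seg) == 0:
        logger.warning("empty normal panel: no breaks will be blacklisted")
        return set()
    io_formats.validate_seg(normal_seg, "normal panel")
    blacklist: set[tuple[str, int]] = set()
    for (_, chrom), grp in normal_seg.groupby(["sample_id", "chromosome"], sort=False):
        ends = grp.sort_values("start")["end"].to_numpy()
        for e in ends[:-1]:
            blacklist.add((str(chrom), int(e)))
    return blacklist


def _blacklist_by_chrom(blacklist) -> dict[str, np.ndarray]:
    by: dict[str, list[int]] = {}
    for chrom, pos in blacklist:
        by.setdefault(str(chrom), []).append(int(pos))
    return {c: np.sort(np.asarray(p)) for c, p in by.items()}


def call_breaks(profile: pd.DataFrame,
                blacklist=frozenset(),
                params: BreakFilterParams | None = None) -> pd.DataFrame:
    """Enumerate and filter candidate breaks for one sample.

    One candidate per adjacent same-chromosome segment pair, with
    ``sas = min(left.num_probes, right.num_probes)`` and
    ``brs = |right.segment_mean - left.segment_mean|``. Status is
    assigned in the order filtered_normal -> filtered_sas ->
    filtered_brs -> retained.
    """
    params = params or BreakFilterParams()
    if len(profile) == 0:
        return pd.DataFrame(columns=["sample_id", "chromosome", "boundary_pos",
                                     "sas", "brs", "status"])
    if profile["sample_id"].nunique() != 1:
        raise ValueError("call_breaks expects the profile of a single sample")
    io_formats.validate_seg(profile, "tumor profile")
    bl = _blacklist_by_chrom(blacklist)
    tol = params.normal_match_tolerance
    rows = []
    sample = profile["sample_id"].iloc[0]
    for chrom, grp in profile.groupby("chromosome", sort=False):
        grp = grp.sort_values("start")
        probes = grp["num_probes"].to_numpy()
        means = grp["segment_mean"].to_numpy(dtype=float)
        ends = grp["end"].to_numpy()
        if len(grp) < 2:
            continue
        sas = np.minimum(probes[:-1], probes[1:])
        brs = np.abs(np.diff(means))
        pos = ends[:-1].astype(np.int64)
        positions = bl.get(str(chrom), np.empty(0, dtype=np.int64))
        for p, s, b in zip(pos, sas, brs):
            if len(positions):
                i = np.searchsorted(positions, p)
                near = min(
                    abs(int(positions[min(i, len(positions) - 1)]) - int(p)),
                    abs(int(positions[max(i - 1, 0)]) - int(p)),
                )
            else:
                near = None
            if near is not None and near <= tol:
                status = "filtered_normal"
            elif s < params.sas_min:
                status = "filtered_sas"
            elif b < params.brs_min:
                status = "filtered_brs"
            else:
                status = "retained"
            rows.append({"sample_id": sample, "chromosome": str(chrom),
                         "boundary_pos": int(p), "sas": int(s),
                         "brs": float(b), "status": status})
    return pd.DataFrame(rows, columns=["sample_id", "chromosome", "boundary_pos",
                                       "sas", "brs", "status"])


def tbl_from_segments(profile: pd.DataFrame, blacklist=frozenset(),
                      params: BreakFilterParams | None = None) -> int:
    """TBL from a segmented profile: the number of retained breaks."""
    catalog = call_breaks(profile, blacklist, params)
    return int((catalog["status"] == "retained").sum())


def tbl_from_sv(records: pd.DataFrame, breakpoints_per_event: int = 2) -> int:
    """TBL from SV calls: breakpoints of unbalanced (DEL/DUP) events.

    A copy-number-changing event creates two genomic breaks, hence the
    default of two breakpoints per record; a one-per-record convention
    is also supported. INS/INV/TRA are balanced and excluded.
    """
    if breakpoints_per_event not in (1, 2):
        raise ValueError("breakpoints_per_event must be 1 or 2")
    if len(records) == 0:
        return 0
    n_events = int(records["sv_type"].isin(UNBALANCED_SV_TYPES).sum())
    return breakpoints_per_event * n_events


def compute_fga(profile: pd.DataFrame, threshold: float = 0.2,
                genome_length: int | None = None) -> float:
    """Fraction of (profiled) genome length with |segment_mean| >= threshold."""
    if len(profile) == 0:
        return 0.0
    lengths = (profile["end"] - profile["start"] + 1).to_numpy(dtype=float)
    altered = np.abs(profile["segment_mean"].to_numpy(dtype=float)) >= threshold
    denom = float(genome_length) if genome_length else float(lengths.sum())
    if denom <= 0:
        return 0.0
    return float(np.clip(lengths[altered].sum() / denom, 0.0, 1.0))


def compute_tmb(mutations: pd.DataFrame, exclude_silent: bool = True,
                per_mb: float | None = None) -> float:
    """Count of (non-silent) small variants, per Mb if a footprint is given."""
    if len(mutations) == 0:
        n = 0
    else:
        df = io_formats.filter_silent(mutations) if exclude_silent else mutations
        n = len(df)
    if per_mb:
        return n / float(per_mb)
    return int(n)


def compute_measure_table(tumor_seg: pd.DataFrame,
                          normal_seg: pd.DataFrame | None = None,
                          sv: pd.DataFrame | None = None,
                          mutations: pd.DataFrame | None = None,
                          clinical: pd.DataFrame | None = None,
                          params: BreakFilterParams | None = None,
                          fga_threshold: float = 0.2,
                          breakpoints_per_event: int = 2) -> pd.DataFrame:
    """Per-sample measure table: tbl, tbl_sv, fga, tmb (+ clinical join).

    The spine of the pipeline: one row per tumor sample of the SEG
    input, joined on ``sample_id`` with clinical covariates when given.
    """
    params = params or BreakFilterParams()
    blacklist = build_normal_blacklist(normal_seg, params) \
        if normal_seg is not None and len(normal_seg) else set()
    rows = []
    sv_by = dict(tuple(sv.groupby("sample_id"))) if sv is not None and len(sv) else {}
    mut_by = dict(tuple(mutations.groupby("sample_id"))) \
        if mutations is not None and len(mutations) else {}
    for sample, profile in tumor_seg.groupby("sample_id", sort=True):
        rows.append({
            "sample_id": sample,
            "tbl": tbl_from_segments(profile, blacklist, params),
            "tbl_sv": tbl_from_sv(sv_by.get(sample, pd.DataFrame(columns=["sv_type"])),
                                  breakpoints_per_event),
            "fga": compute_fga(profile, fga_threshold),
            "tmb": compute_tmb(mut_by.get(sample,
                                          pd.DataFrame(columns=io_formats.MUTATION_COLUMNS))),
        })
    table = pd.DataFrame(rows)
    if clinical is not None and len(clinical):
        table = table.merge(clinical, on="sample_id", how="left")
    return table
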