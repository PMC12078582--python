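"""Screen genomic alterations for association with instability measures.

Per gene and alteration type (non-silent SNVs; SV breakpoints falling
inside the gene) and per chromosome arm (gains/losses at a +/-0.2
length-weighted mean log2 ratio), samples are split into altered vs
wild-type and the measure compared with a two-sided Mann-Whitney U
test. MSI samples are excluded by default (their SNV excess confounds
the screen), features need at least 10 altered and 10 wild-type
samples, and the measure is corrected for the local burden of the
tested gene — in-gene SNVs are subtracted from TMB, in-gene SV
breakpoints from TBL — so a gene cannot associate with a genome-wide
burden merely by contributing to it. The fold change reported is the
log2 ratio of pseudocounted group medians.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import io_formats
from .landscape import mann_whitney

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationConfig",
    "AlterationMatrix",
    "build_alteration_matrix",
    "corrected_measure",
    "minimal_significant_p",
    "differential_measure_test",
]

#: measure -> alteration kind whose local burden is subtracted
BURDEN_CORRECTION = {"tmb": "SNV", "tbl": "SV", "tbl_sv": "SV"}
#: pseudocount for the median fold change, per measure scale
FC_PSEUDOCOUNT = {"fga": 1e-3}
DEFAULT_PSEUDOCOUNT = 1.0


@dataclass(frozen=True)
class AssociationConfig:
    alpha: float = 0.05
    min_group: int = 10
    msi_excluded: bool = True
    multiple_testing: str = "bh"   # "bh" (per-screen FDR) or "bonferroni"
    m: int | None = None           # number of tests for the Bonferroni threshold

    def __post_init__(self) -> None:
        if self.multiple_testing not in ("bh", "bonferroni"):
            raise ValueError("multiple_testing must be 'bh' or 'bonferroni'")


def minimal_significant_p(alpha: float = 0.05, m: int = 20000) -> float:
    """Bonferroni threshold alpha / m (the genome-wide screen's floor)."""
    if m < 1:
        raise ValueError("m must be a positive number of tests")
    return alpha / m


@dataclass
class AlterationMatrix:
    """Binary alteration flags plus local burden counts per sample."""

    flags: pd.DataFrame                     # samples x features, boolean
    burdens: dict[str, pd.DataFrame]        # kind -> samples x genes counts
    features: pd.DataFrame                  # feature, unit, kind


def _point_in_gene_counts(points: pd.DataFrame, genes: pd.DataFrame,
                          samples: list) -> pd.DataFrame:
    """Count points (sample, chromosome, position; 1-based) per sample x gene."""
    counts = pd.DataFrame(0, index=pd.Index(samples, name="sample_id"),
                          columns=genes["gene"], dtype=np.int64)
    for chrom, ggrp in genes.groupby("chromosome"):
        pts = points[points["chromosome"] == chrom]
        if not len(pts):
            continue
        for _, g in ggrp.iterrows():
            inside = pts[(pts["position"] >= g["start"]) & (pts["position"] <= g["end"])]
            if len(inside):
                vc = inside.groupby("sample_id").size()
                counts.loc[vc.index.intersection(counts.index), g["gene"]] += \
                    vc[vc.index.isin(counts.index)].to_numpy()
    return counts


def arm_calls(segments: pd.DataFrame, arms: pd.DataFrame,
              threshold: float = 0.2) -> pd.DataFrame:
    """Arm-level gain/loss calls from the length-weighted mean segment_mean.

    ``arms`` needs columns arm, chromosome, start, end (1-based
    inclusive). Returns samples x arm mean log2 ratio.
    """
    samples = sorted(segments["sample_id"].unique())
    out = pd.DataFrame(np.nan, index=pd.Index(samples, name="sample_id"),
                       columns=arms["arm"])
    for _, a in arms.iterrows():
        seg = segments[segments["chromosome"] == a["chromosome"]]
        lo = np.maximum(seg["start"].to_numpy(), a["start"])
        hi = np.minimum(seg["end"].to_numpy(), a["end"])
        w = np.maximum(hi - lo + 1, 0).astype(float)
        df = pd.DataFrame({"sample_id": seg["sample_id"].to_numpy(), "w": w,
                           "wm": w * seg["segment_mean"].to_numpy()})
        agg = df.groupby("sample_id").sum()
        mean = agg["wm"] / agg["w"].replace(0, np.nan)
        out.loc[mean.index, a["arm"]] = mean
    return out


def build_alteration_matrix(mutations: pd.DataFrame | None = None,
                            sv: pd.DataFrame | None = None,
                            genes: pd.DataFrame | None = None,
                            segments: pd.DataFrame | None = None,
                            arms: pd.DataFrame | None = None,
                            samples=None,
                            exclude_silent: bool = True,
                            arm_threshold: float = 0.2) -> AlterationMatrix:
    """Assemble per-sample alteration flags and local burden counts.

    Gene-level SNV flags require >= 1 non-silent SNV in the gene;
    gene-level SV flags require >= 1 SV breakpoint (either end of the
    call) within the gene interval, which needs a gene coordinate
    table. Arm gains/losses come from segments vs a +/-threshold rule.
    """
    if samples is None:
        pools = []
        for df, col in ((mutations, "sample_id"), (sv, "sample_id"),
                        (segments, "sample_id")):
            if df is not None and len(df):
                pools.append(df[col].unique())
        samples = sorted(set(np.concatenate(pools))) if pools else []
    samples = list(samples)
    flag_blocks, feat_rows = [], []
    burdens: dict[str, pd.DataFrame] = {}

    if mutations is not None and len(mutations):
        mut = io_formats.filter_silent(mutations) if exclude_silent else mutations
        counts = (mut.groupby(["sample_id", "gene"]).size().unstack(fill_value=0)
                  .reindex(index=samples, fill_value=0))
        counts.index.name = "sample_id"
        burdens["SNV"] = counts.astype(np.int64)
        blk = (counts > 0)
        blk.columns = [f"{g}|SNV" for g in counts.columns]
        flag_blocks.append(blk)
        feat_rows += [{"feature": c, "unit": c.split("|")[0], "kind": "SNV"}
                      for c in blk.columns]

    if sv is not None and len(sv):
        if genes is None:
            logger.warning("SV records given without a gene coordinate map; "
                           "SV-to-gene assignment skipped")
        else:
            pts = pd.concat([
                pd.DataFrame({"sample_id": sv["sample_id"], "chromosome": sv["chrom1"],
                              "position": sv["start1"].astype(int) + 1}),
                pd.DataFrame({"sample_id": sv["sample_id"], "chromosome": sv["chrom2"],
                              "position": sv["start2"].astype(int) + 1}),
            ], ignore_index=True)
            counts = _point_in_gene_counts(pts, genes, samples)
            burdens["SV"] = counts
            blk = (counts > 0)
            blk.columns = [f"{g}|SV" for g in counts.columns]
            flag_blocks.append(blk)
            feat_rows += [{"feature": c, "unit": c.split("|")[0], "kind": "SV"}
                          for c in blk.columns]

    if segments is not None and arms is not None and len(arms):
        means = arm_calls(segments, arms, arm_threshold).reindex(index=samples)
        gain = (means > arm_threshold).fillna(False)
        loss = (means < -arm_threshold).fillna(False)
        gain.columns = [f"{a}|gain" for a in means.columns]
        loss.columns = [f"{a}|loss" for a in means.columns]
        flag_blocks += [gain, loss]
        feat_rows += [{"feature": c, "unit": c.split("|")[0], "kind": "SCNA"}
                      for c in list(gain.columns) + list(loss.columns)]

    flags = pd.concat(flag_blocks, axis=1) if flag_blocks else \
        pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    flags = flags.reindex(index=samples).fillna(False).astype(bool)
    flags.index.name = "sample_id"
    return AlterationMatrix(flags=flags, burdens=burdens,
                            features=pd.DataFrame(feat_rows, columns=["feature", "unit", "kind"]))


def corrected_measure(values: pd.Series, burden: pd.Series) -> pd.Series:
    """Subtract the in-gene local burden from a count measure, floored at 0."""
    out = values.astype(float) - burden.reindex(values.index).fillna(0).astype(float)
    return out.clip(lower=0.0)


def differential_measure_test(matrix: AlterationMatrix, measures: pd.DataFrame,
                              measure: str = "tbl",
                              config: AssociationConfig | None = None) -> pd.DataFrame:
    """Mann-Whitney screen of every feature against one measure.

    ``measures`` is indexed (or indexable) by sample_id with a column
    per measure and optionally ``msi_status``. The local-burden
    correction applies only when the alteration kind matches the
    measure (SNV for TMB, SV for TBL); FGA is never corrected.
    Adjustment is per (measure, alteration-kind) screen: BH by default,
    or the Bonferroni ``alpha / m`` floor.
    """
    config = config or AssociationConfig()
    ms = measures.set_index("sample_id") if "sample_id" in measures.columns else measures
    if config.msi_excluded and "msi_status" in ms.columns:
        ms = ms[ms["msi_status"] != "MSI"]
    common = matrix.flags.index.intersection(ms.index)
    flags = matrix.flags.loc[common]
    vals = ms.loc[common, measure].astype(float)
    pc = FC_PSEUDOCOUNT.get(measure, DEFAULT_PSEUDOCOUNT)
    burden_kind = BURDEN_CORRECTION.get(measure)
    kind_of = dict(zip(matrix.features["feature"], matrix.features["kind"]))
    unit_of = dict(zip(matrix.features["feature"], matrix.features["unit"]))

    rows = []
    for feature in flags.columns:
        alt = flags[feature]
        n_alt, n_wt = int(alt.sum()), int((~alt).sum())
        if n_alt == 0 or n_wt == 0:
            logger.info("feature %s is all-%s; skipped", feature,
                        "altered" if n_wt == 0 else "WT")
            continue
        if n_alt < config.min_group or n_wt < config.min_group:
            continue
        kind = kind_of.get(feature)
        v = vals
        if burden_kind is not None and kind == burden_kind and burden_kind in matrix.burdens:
            b = matrix.burdens[burden_kind]
            gene = unit_of[feature]
            if gene in b.columns:
                v = corrected_measure(vals, b[gene])
        a, w = v[alt].to_numpy(), v[~alt].to_numpy()
        u, p = mann_whitney(a, w)
        rows.append({
            "feature": feature, "unit": unit_of.get(feature), "kind": kind,
            "measure": measure, "n_altered": n_alt, "n_wt": n_wt,
            "log2_fc": float(np.log2((np.median(a) + pc) / (np.median(w) + pc))),
            "p": p,
        })
    out = pd.DataFrame(rows, columns=["feature", "unit", "kind", "measure",
                                      "n_altered", "n_wt", "log2_fc", "p"])
    if len(out):
        out["p_adj"] = np.nan
        for kind, idx in out.groupby("kind").groups.items():
            pvals = out.loc[idx, "p"]
            if config.multiple_testing == "bh":
                out.loc[idx, "p_adj"] = stats.false_discovery_control(pvals)
            else:
                m = config.m or len(pvals)
                out.loc[idx, "p_adj"] = np.minimum(pvals * m, 1.0)
    else:
        out["p_adj"] = []
    return out
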