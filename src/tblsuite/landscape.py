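"""Inter/intra-cancer-type variability and cross-measure relationships.

The standardized IQR ranks a measure over the *pooled* pan-cancer
cohort, takes the interquartile range of those ranks within each cancer
type, and divides by the total range of pooled ranks. Being rank-based
it is invariant under strictly monotone transforms of the raw measure
and comparable between measures with different scales.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["standardized_iqr", "correlate_measures", "group_association", "mann_whitney"]

STAGE_ORDER = {"I": 1, "II": 2, "III": 3, "IV": 4}


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U of x vs y: returns (U of x, p).

    Uses the exact null distribution whenever there are no ties and the
    comparison is small enough, the tie-corrected normal approximation
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (not ties and len(x) * len(y) <= 20000) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def standardized_iqr(values, groups, quantile_method: str = "linear") -> pd.DataFrame:
    """Per-group scaled IQR of pooled ranks, with the group median.

    Ranks are average ranks over the pooled vector; the per-group IQR of
    ranks (type-7 / linear-interpolation quantiles by default) is
    divided by (max rank - min rank) of the pooled vector. Groups with
    fewer than two samples, or a pooled vector with zero rank range
    (all values tied), yield a missing score.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(values) < 2:
        raise ValueError("standardized_iqr needs at least two samples overall")
    ranks = stats.rankdata(values, method="average")
    rank_range = ranks.max() - ranks.min()
    rows = []
    for g in pd.unique(groups):
        mask = groups == g
        med = float(np.median(values[mask]))
        if mask.sum() < 2 or rank_range == 0:
            score = np.nan
        else:
            q1, q3 = np.quantile(ranks[mask], [0.25, 0.75], method=quantile_method)
            score = float((q3 - q1) / rank_range)
        rows.append({"group": g, "n": int(mask.sum()), "median": med,
                     "standardized_iqr": score})
    return pd.DataFrame(rows)


def correlate_measures(table: pd.DataFrame, x: str, y: str) -> tuple[float, float]:
    """Pearson r (and r^2, as commonly reported) on complete pairs."""
    sub = table[[x, y]].dropna()
    r = float(stats.pearsonr(sub[x], sub[y]).statistic)
    return r, r * r


def group_association(table: pd.DataFrame, measure: str, grouping: str,
                      by: str = "cancer_type", min_group: int = 3) -> pd.DataFrame:
    """Association of a measure with MSI status or ordinal stage, per cancer type.

    ``grouping='msi_status'``: two-group Mann-Whitney (MSI vs MSS) with
    direction (sign of the median difference). ``grouping='stage'``:
    all pairwise Mann-Whitney comparisons plus a rank-based monotonic
    trend (Kendall tau of the measure against ordinal stage).
    Benjamini-Hochberg adjustment is applied across cancer types within
    each comparison label. Comparisons with a group below ``min_group``
    samples are skipped and logged.
    """
    if grouping not in ("msi_status", "stage"):
        raise ValueError("grouping must be 'msi_status' or 'stage'")
    rows = []
    for ct, grp in table.groupby(by):
        sub = grp[[measure, grouping]].dropna()
        sub = sub[sub[grouping] != "NA"]
        if grouping == "msi_status":
            mss = sub.loc[sub[grouping] == "MSS", measure].to_numpy()
            msi = sub.loc[sub[grouping] == "MSI", measure].to_numpy()
            if min(len(mss), len(msi)) < min_group:
                logger.info("%s: MSI comparison skipped (group below %d)", ct, min_group)
                continue
            u, p = mann_whitney(msi, mss)
            rows.append({by: ct, "comparison": "MSI_vs_MSS", "n1": len(msi),
                         "n2": len(mss), "statistic": u,
                         "direction": float(np.sign(np.median(msi) - np.median(mss))),
                         "p": p})
        else:
            present = [s for s in STAGE_ORDER if (sub[grouping] == s).sum() >= min_group]
            for i, s1 in enumerate(present):
                for s2 in present[i + 1:]:
                    a = sub.loc[sub[grouping] == s2, measure].to_numpy()
                    b = sub.loc[sub[grouping] == s1, measure].to_numpy()
                    u, p = mann_whitney(a, b)
                    rows.append({by: ct, "comparison": f"{s2}_vs_{s1}", "n1": len(a),
                                 "n2": len(b), "statistic": u,
                                 "direction": float(np.sign(np.median(a) - np.median(b))),
                                 "p": p})
            ord_stage = sub[grouping].map(STAGE_ORDER)
            if ord_stage.nunique() >= 2 and len(sub) >= min_group:
                tau = stats.kendalltau(sub[measure], ord_stage)
                rows.append({by: ct, "comparison": "trend", "n1": len(sub), "n2": len(sub),
                             "statistic": float(tau.statistic),
                             "direction": float(np.sign(tau.statistic)), "p": float(tau.pvalue)})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = np.nan
        for comp, idx in out.groupby("comparison").groups.items():
            out.loc[idx, "p_adj"] = stats.false_discovery_control(out.loc[idx, "p"])
    return out
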