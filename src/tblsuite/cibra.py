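"""Transcriptome-impact scoring of a genomic-instability measure.

Samples of one cancer type are ranked on the measure in descending
order and annotated HIGH (first quartile), LOW (last quartile) or
INTERMEDIATE. Ten random subsamples of 10 HIGH vs 10 LOW samples each
undergo a two-group differential-expression (DE) analysis; the impact
("proportion") score of a subsample is the fraction of tested genes
called differentially expressed. Significance of the observed scores
is assessed with a Mann-Whitney U test against a reference
distribution of scores from random permutations of the whole cohort
(10 cases vs 10 controls drawn irrespective of group labels).

The DE step is a *contract*: any callable mapping
``(counts, case, control) -> DataFrame[log2_fc, p, p_adj, base_mean]``
can be plugged in. The reference implementation is a two-group
negative-binomial Wald test: median-of-ratios library-size
normalization, per-gene method-of-moments dispersion shrunk toward a
``a0 + a1/mean`` trend, and a t reference distribution with
``n1 + n0 - 2`` degrees of freedom. Genes below a mean normalized
count floor are excluded before Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .landscape import mann_whitney

__all__ = [
    "annotate_groups",
    "draw_subsamples",
    "size_factors",
    "differential_expression",
    "proportion_score",
    "permutation_reference",
    "impact_significance",
    "cibra_analysis",
    "ImpactScore",
    "CibraResult",
]


@dataclass(frozen=True)
class ImpactScore:
    subsample_id: int
    proportion_score: float
    n_genes_tested: int


@dataclass
class CibraResult:
    scores: list[ImpactScore]
    reference: np.ndarray
    p: float
    direction: float
    de_results: list[pd.DataFrame] = field(default_factory=list)

    @property
    def score_values(self) -> np.ndarray:
        return np.array([s.proportion_score for s in self.scores])


def annotate_groups(measure: pd.Series, min_high: int = 10) -> pd.DataFrame:
    """Quartile annotation of one cancer type's measure values.

    Samples are sorted descending (ties broken by sample id, so the
    annotation is stable across runs); the first ``n // 4`` samples are
    HIGH, the last ``n // 4`` LOW, the rest INTERMEDIATE. The frame's
    ``attrs['eligible']`` flags whether at least ``min_high`` HIGH
    samples are available for impact analysis.
    """
    s = pd.Series(measure)
    order = s.reset_index()
    order.columns = ["sample_id", "value"]
    order = order.sort_values(["value", "sample_id"], ascending=[False, True])
    n = len(order)
    q = n // 4
    group = np.array(["INTERMEDIATE"] * n, dtype=object)
    if q:
        group[:q] = "HIGH"
        group[n - q:] = "LOW"
    out = pd.DataFrame({"sample_id": order["sample_id"].to_numpy(), "group": group})
    out.attrs["eligible"] = bool(q >= min_high)
    return out


def draw_subsamples(annotation: pd.DataFrame, k: int = 10, arm_size: int = 10,
                    seed: int | None = None,
                    rng: np.random.Generator | None = None) -> list[tuple[list, list]]:
    """Draw ``k`` (HIGH-set, LOW-set) subsamples without replacement per arm.

    Partial overlap between subsamples is allowed. When each arm holds
    exactly ``arm_size`` samples, a single subsample containing all of
    them is returned, since no non-identical subsets exist.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    high = annotation.loc[annotation["group"] == "HIGH", "sample_id"].tolist()
    low = annotation.loc[annotation["group"] == "LOW", "sample_id"].tolist()
    if len(high) < arm_size or len(low) < arm_size:
        raise ValueError(
            f"need at least {arm_size} samples per arm (have {len(high)} HIGH, {len(low)} LOW)"
        )
    if len(high) == arm_size and len(low) == arm_size:
        return [(list(high), list(low))]
    out = []
    for _ in range(k):
        h = [high[i] for i in rng.choice(len(high), size=arm_size, replace=False)]
        l = [low[i] for i in rng.choice(len(low), size=arm_size, replace=False)]
        out.append((h, l))
    return out


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios library-size factors (geometric mean reference).

    Falls back to depth ratios when too few genes are expressed in every
    sample. Factors are scaled to geometric mean 1.
    """
    counts = np.asarray(counts, dtype=float)
    expressed = np.all(counts > 0, axis=1)
    if expressed.sum() >= 10:
        logref = np.log(counts[expressed]).mean(axis=1)
        s = np.exp(np.median(np.log(counts[expressed]) - logref[:, None], axis=0))
    else:
        totals = counts.sum(axis=0)
        s = totals / np.exp(np.mean(np.log(np.maximum(totals, 1.0))))
    return s / np.exp(np.mean(np.log(s)))


def differential_expression(counts: pd.DataFrame, case, control,
                            min_mean: float = 1.0,
                            shrink_weight: float = 0.25) -> pd.DataFrame:
    """Reference two-group negative-binomial Wald test (see module docs).

    ``counts`` is genes x samples (raw integers); ``case`` / ``control``
    are disjoint sample-name lists with at least two members each.
    Returns one row per gene passing the mean-normalized-count floor,
    with columns base_mean, log2_fc, p, p_adj.
    """
    case, control = list(case), list(control)
    if set(case) & set(control):
        raise ValueError("case and control sets overlap")
    if len(case) < 2 or len(control) < 2:
        raise ValueError("need at least two samples per arm")
    sub = counts[case + control].to_numpy(dtype=float)
    zero = sub.sum(axis=0) == 0
    if zero.any():
        bad = [s for s, z in zip(case + control, zero) if z]
        raise ValueError(f"sample(s) with zero total counts: {', '.join(map(str, bad))}")
    n1, n0 = len(case), len(control)
    s = size_factors(sub)
    q = sub / s
    q1, q0 = q[:, :n1], q[:, n1:]
    m1, m0 = q1.mean(axis=1), q0.mean(axis=1)
    base = q.mean(axis=1)
    keep = base >= min_mean

    # method-of-moments dispersion, pooled within groups, shrunk to a 1/mu trend
    v = ((n1 - 1) * q1.var(axis=1, ddof=1) + (n0 - 1) * q0.var(axis=1, ddof=1)) / (n1 + n0 - 2)
    mbar = (n1 * m1 + n0 * m0) / (n1 + n0)
    inv_s_mean = float(np.mean(1.0 / s))
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mom = (v - mbar * inv_s_mean) / np.maximum(mbar, 1e-12) ** 2
    fit_mask = keep & (alpha_mom > 0) & (mbar > 0)
    if fit_mask.sum() >= 10:
        X = np.column_stack([np.ones(fit_mask.sum()), 1.0 / mbar[fit_mask]])
        coef, *_ = np.linalg.lstsq(X, alpha_mom[fit_mask], rcond=None)
        a0, a1 = np.maximum(coef, 0.0)
        if a0 == 0.0 and a1 == 0.0:
            a0 = float(np.median(alpha_mom[fit_mask]))
    else:
        a0, a1 = (float(np.median(alpha_mom[fit_mask])) if fit_mask.any() else 0.01), 0.0
    trend = a0 + a1 / np.maximum(mbar, 1e-12)
    lo, hi = 1e-8, 10.0
    alpha = np.exp(
        (1.0 - shrink_weight) * np.log(np.clip(trend, lo, hi))
        + shrink_weight * np.log(np.clip(alpha_mom, lo, hi))
    )

    inv_s1 = float(np.sum(1.0 / s[:n1]))
    inv_s0 = float(np.sum(1.0 / s[n1:]))
    c0 = 0.5  # prior normalized count, stabilizes empty groups
    lfc = np.log2((m1 + c0) / (m0 + c0))
    var_log = (inv_s1 / (n1 ** 2 * (m1 + c0)) + alpha / n1
               + inv_s0 / (n0 ** 2 * (m0 + c0)) + alpha / n0)
    z = np.log((m1 + c0) / (m0 + c0)) / np.sqrt(var_log)
    p = 2.0 * stats.t.sf(np.abs(z), df=n1 + n0 - 2)

    out = pd.DataFrame({
        "base_mean": base[keep],
        "log2_fc": lfc[keep],
        "p": p[keep],
    }, index=counts.index[keep])
    out["p_adj"] = stats.false_discovery_control(out["p"]) if len(out) else []
    out.index.name = "gene"
    return out


def proportion_score(de: pd.DataFrame, alpha: float = 0.05,
                     adjusted: bool = True) -> float:
    """Fraction of tested genes called differentially expressed.

    The default criterion is ``p_adj < alpha``; ``adjusted=False``
    applies the threshold to the raw p-value instead (a documented
    config option; useful when a non-degenerate null score distribution
    is required, e.g. for calibration studies).
    """
    if len(de) == 0:
        return 0.0
    col = "p_adj" if adjusted else "p"
    return float((de[col] < alpha).mean())


def permutation_reference(counts: pd.DataFrame, samples, n_perm: int = 1000,
                          arm_size: int = 10, seed: int | None = None,
                          rng: np.random.Generator | None = None,
                          de_func=differential_expression,
                          alpha: float = 0.05, adjusted: bool = True,
                          **de_kwargs) -> np.ndarray:
    """Reference distribution of impact scores from random permutations.

    Each permutation draws ``2 * arm_size`` samples uniformly without
    replacement from *all* given samples — group labels, including
    INTERMEDIATE, are ignored — and scores the resulting case/control
    split. ``n_perm`` defaults to 1000; 100 is the documented choice
    for small cohorts.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    samples = list(samples)
    if len(samples) < 2 * arm_size:
        raise ValueError("not enough samples for a permutation draw")
    scores = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.choice(len(samples), size=2 * arm_size, replace=False)
        case = [samples[j] for j in idx[:arm_size]]
        ctrl = [samples[j] for j in idx[arm_size:]]
        de = de_func(counts, case, ctrl, **de_kwargs)
        scores[i] = proportion_score(de, alpha=alpha, adjusted=adjusted)
    return scores


def impact_significance(observed, reference) -> tuple[float, float]:
    """Two-sided Mann-Whitney of observed subsample scores vs the reference.

    Returns ``(p, direction)``; direction is the sign of the median
    difference (+1 when observed scores exceed the reference).
    """
    observed = np.asarray(observed, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if len(observed) < 1:
        raise ValueError("need at least one observed score")
    if len(reference) < 1:
        raise ValueError("need a non-empty reference distribution")
    _, p = mann_whitney(observed, reference)
    direction = float(np.sign(np.median(observed) - np.median(reference)))
    return p, direction


def cibra_analysis(counts: pd.DataFrame, measure: pd.Series, k: int = 10,
                   arm_size: int = 10, n_perm: int = 1000, seed: int = 0,
                   alpha: float = 0.05, adjusted: bool = True,
                   de_func=differential_expression, min_high: int = 10,
                   keep_de: bool = True, **de_kwargs) -> CibraResult:
    """Full impact analysis of one cancer type for one measure."""
    annotation = annotate_groups(measure, min_high=min_high)
    if not annotation.attrs["eligible"]:
        raise ValueError(f"fewer than {min_high} HIGH samples: cancer type ineligible")
    rng = np.random.default_rng(seed)
    subs = draw_subsamples(annotation, k=k, arm_size=arm_size, rng=rng)
    scores, de_results = [], []
    for i, (high, low) in enumerate(subs):
        de = de_func(counts, high, low, **de_kwargs)
        scores.append(ImpactScore(i, proportion_score(de, alpha, adjusted), len(de)))
        if keep_de:
            de_results.append(de)
    reference = permutation_reference(
        counts, list(measure.index), n_perm=n_perm, arm_size=arm_size, rng=rng,
        de_func=de_func, alpha=alpha, adjusted=adjusted, **de_kwargs)
    p, direction = impact_significance([s.proportion_score for s in scores], reference)
    return CibraResult(scores, reference, p, direction, de_results)
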