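"""Combine per-subsample DE results and run preranked gene-set enrichment.

Genes are ranked by ``score = sgn(mean_fc) * -log10(mean_p_adj)``,
where the means are taken over the subsample DE results, so the list
runs from up-regulated-with-highest-significance through unchanged to
down-regulated-with-highest-significance. Enrichment uses the weighted
Kolmogorov-Smirnov running sum on that ranking with a gene-permutation
null (random sets of matching size), which is the appropriate null for
a preranked input.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["combine_and_rank", "enrichment_score", "preranked_gsea"]


def combine_and_rank(de_results: list[pd.DataFrame]) -> pd.DataFrame:
    """Average DE results over subsamples and rank genes by signed score.

    The gene universe is the intersection of the inputs (a mismatch is
    logged). A mean adjusted p of exactly 0 is clamped to the smallest
    positive float before the log; ``sgn(0) = 0``, so a zero mean fold
    change scores 0 regardless of significance. Ordering is descending
    by score with ties broken by gene name.
    """
    if not de_results:
        raise ValueError("no DE results to combine")
    universe = de_results[0].index
    for de in de_results[1:]:
        universe = universe.intersection(de.index)
    if any(len(de) != len(universe) for de in de_results):
        logger.info("DE results differ in gene universe; using the %d-gene intersection",
                    len(universe))
    fc = np.mean([de.loc[universe, "log2_fc"].to_numpy() for de in de_results], axis=0)
    padj = np.mean([de.loc[universe, "p_adj"].to_numpy() for de in de_results], axis=0)
    score = np.sign(fc) * -np.log10(np.clip(padj, np.finfo(float).tiny, None))
    out = pd.DataFrame({"gene": universe, "mean_fc": fc, "mean_p_adj": padj,
                        "score": score})
    return out.sort_values(["score", "gene"], ascending=[False, True]).reset_index(drop=True)


def enrichment_score(scores: np.ndarray, hits: np.ndarray, weight: float = 1.0) -> float:
    """Weighted KS running-sum enrichment score for one gene set.

    ``scores`` must be in ranked (descending) order and ``hits`` a
    boolean mask of set membership in that order. Hits advance the sum
    by ``|score|^weight`` (normalized); misses retreat by
    ``1 / (N - Nh)``. The ES is the running-sum value of maximal
    absolute deviation from zero. When all hit weights vanish the
    unweighted statistic is used.
    """
    scores = np.asarray(scores, dtype=float)
    hits = np.asarray(hits, dtype=bool)
    n = len(scores)
    nh = int(hits.sum())
    if nh == 0 or nh == n:
        raise ValueError("gene set must hit a strict, non-empty subset of the ranking")
    w = np.abs(scores) ** weight * hits
    total = w.sum()
    if total == 0:
        w = hits.astype(float)
        total = float(nh)
    dev = np.cumsum(w / total - (~hits) / (n - nh))
    return float(dev[np.argmax(np.abs(dev))])


def preranked_gsea(ranked: pd.DataFrame, gene_sets: dict, weight: float = 1.0,
                   n_perm: int = 1000, seed: int | None = 0,
                   min_size: int = 5, max_size: int = 500) -> pd.DataFrame:
    """Preranked GSEA over a ranked gene table (from :func:`combine_and_rank`).

    Gene sets are filtered to an overlap size within [min_size,
    max_size]; sets with no overlap (or covering the whole universe)
    are dropped with a warning. The null permutes gene labels: for
    each set, ``n_perm`` random same-size gene subsets are scored. The
    normalized enrichment score divides the ES by the mean |permuted
    ES| of matching sign, and the p-value is the matching-sign
    one-tailed permutation frequency (with the +1 correction).
    Benjamini-Hochberg adjustment is applied across sets.
    """
    genes = ranked["gene"].to_numpy()
    scores = ranked["score"].to_numpy(dtype=float)
    pos = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    rng = np.random.default_rng(seed)
    rows = []
    for name, members in gene_sets.items():
        idx = sorted({pos[g] for g in members if g in pos})
        nh = len(idx)
        if nh == 0:
            logger.warning("gene set %s has no overlap with the ranking; dropped", name)
            continue
        if nh == n:
            logger.warning("gene set %s covers the whole universe; dropped", name)
            continue
        if not min_size <= nh <= max_size:
            continue
        hits = np.zeros(n, dtype=bool)
        hits[idx] = True
        es = enrichment_score(scores, hits, weight)

        perm_es = np.empty(n_perm)
        mask = np.zeros(n, dtype=bool)
        for i in range(n_perm):
            mask[:] = False
            mask[rng.choice(n, size=nh, replace=False)] = True
            perm_es[i] = enrichment_score(scores, mask, weight)
        same = perm_es[perm_es >= 0] if es >= 0 else perm_es[perm_es < 0]
        if len(same):
            p = (1.0 + np.sum(np.abs(same) >= abs(es))) / (1.0 + len(same))
            nes = es / np.mean(np.abs(same))
        else:
            p, nes = 1.0, np.nan
        rows.append({"gene_set": name, "size": nh, "es": es, "nes": nes, "p": p,
                     "direction": "up" if es >= 0 else "down"})
    out = pd.DataFrame(rows, columns=["gene_set", "size", "es", "nes", "p", "direction"])
    if len(out):
        out["p_adj"] = stats.false_discovery_control(out["p"])
    else:
        out["p_adj"] = []
    return out
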