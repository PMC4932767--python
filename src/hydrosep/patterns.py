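"""k-mer pattern statistics: occurrence, Markov background, enrichment.

Overlapping k-mers (k = 2..5) are counted per pool and normalised to
frequencies of occurrence (FO).  Pool-specific enrichment compares a
pattern's FO in a focal pool against (i) the union of all remaining pools
and (ii) the remaining pools generated by the same strategy (GBSS), with
50x / 500x fold flags, a one-sided Fisher exact test on the 2x2 k-mer
contingency table and Benjamini-Hochberg FDR correction within each
(pool, k) family.  A simple add-one-smoothed Markov chain provides
background pattern probabilities.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .pools import PeptidePool
from .scales import AA_ALPHABETICAL

K_MIN, K_MAX = 2, 5
FLAG50_FOLD = 50.0
FLAG500_FOLD = 500.0


class PatternError(ValueError):
    pass


def count_kmers(pool: PeptidePool, k: int) -> tuple[dict[str, int], dict[str, float]]:
    """Overlapping k-mer counts across all peptides, plus FO normalised to 1."""
    if not (K_MIN <= k <= K_MAX):
        raise PatternError(f"k = {k} outside {K_MIN}..{K_MAX}")
    if not pool.records:
        raise PatternError(f"pool {pool.label!r} is empty")
    counts: Counter[str] = Counter()
    for seq in pool.sequences():
        for i in range(len(seq) - k + 1):
            counts[seq[i:i + k]] += 1
    total = sum(counts.values())
    fo = {p: c / total for p, c in counts.items()} if total else {}
    return dict(counts), fo


@dataclass
class MarkovModel:
    """Add-one-smoothed Markov chain over the 20 amino acids."""

    order: int
    initial: dict[str, float]
    transitions: dict[str, dict[str, float]]

    def pattern_probability(self, pattern: str) -> float:
        """p(a1) * prod p(a_{i+1} | preceding *order* residues)."""
        if not pattern:
            raise PatternError("empty pattern")
        p = self.initial[pattern[0]]
        for i in range(1, len(pattern)):
            ctx = pattern[max(0, i - self.order):i] if self.order > 0 else ""
            p *= self.transitions[ctx][pattern[i]]
        return p


def fit_markov(pool: PeptidePool, order: int = 1) -> MarkovModel:
    """Maximum-likelihood chain with add-one smoothing (order >= 0)."""
    if order < 0:
        raise PatternError("order must be >= 0")
    if not pool.records:
        raise PatternError(f"pool {pool.label!r} is empty")
    comp: Counter[str] = Counter()
    for seq in pool.sequences():
        comp.update(seq)
    total = sum(comp.values())
    initial = {
        a: (comp.get(a, 0) + 1) / (total + 20) for a in AA_ALPHABETICAL
    }
    transitions: dict[str, dict[str, float]] = {}
    if order == 0:
        transitions[""] = dict(initial)
    else:
        trans_counts: dict[str, Counter[str]] = {}
        for seq in pool.sequences():
            for i in range(1, len(seq)):
                ctx = seq[max(0, i - order):i]
                trans_counts.setdefault(ctx, Counter())[seq[i]] += 1
        # every context seen in data gets a smoothed conditional; unseen
        # contexts fall back to the (smoothed) composition
        class _Fallback(dict):
            def __missing__(self, ctx: str) -> dict[str, float]:
                return dict(initial)

        transitions = _Fallback()
        for ctx, cnt in trans_counts.items():
            t = sum(cnt.values())
            transitions[ctx] = {
                a: (cnt.get(a, 0) + 1) / (t + 20) for a in AA_ALPHABETICAL
            }
        # shorter-than-order prefixes of patterns need their contexts too
        for seq in pool.sequences():
            for i in range(1, min(order, len(seq))):
                ctx = seq[:i]
                transitions[ctx]  # touch to materialise fallback lazily
    return MarkovModel(order=order, initial=initial, transitions=transitions)


def coverage_by_length(
    pools: Mapping[str, PeptidePool], k_range: Sequence[int] = range(K_MIN, K_MAX + 1)
) -> dict[int, float]:
    """Fraction of observed patterns (union over pools) present in every pool."""
    if len(pools) < 2:
        raise PatternError("need at least 2 pools")
    out: dict[int, float] = {}
    for k in k_range:
        per_pool = [set(count_kmers(p, k)[0]) for p in pools.values()]
        union = set().union(*per_pool)
        if not union:
            out[k] = 0.0
            continue
        everywhere = set.intersection(*per_pool)
        out[k] = len(everywhere) / len(union)
    return out


@dataclass(frozen=True)
class PatternStat:
    pattern: str
    pool: str
    count: int
    fo_pool: float
    fo_remaining: float
    fo_remaining_same_strategy: float
    fold_all: float
    fold_gbss: float
    p: float
    p_adj: float
    flag50: bool
    flag500: bool


def _fisher_greater_pvalues(
    c_pool: np.ndarray, total_pool: int, c_ref: np.ndarray, total_ref: int
) -> np.ndarray:
    """One-sided (enrichment) Fisher exact p-values, vectorised.

    The p-value of the 2x2 table [[c, total_pool - c], [r, total_ref - r]]
    with fixed margins equals the hypergeometric upper tail
    P[X >= c] with X ~ Hypergeom(M = total_pool + total_ref,
    n = c + r, N = total_pool).
    """
    M = total_pool + total_ref
    n = c_pool + c_ref
    return hypergeom.sf(c_pool - 1, M, n, total_pool)


def enrichment_table(
    pools: Mapping[str, PeptidePool],
    k: int,
    alpha: float = 0.05,
    include_focal_in_reference: bool = False,
) -> pd.DataFrame:
    """Per-pool pattern enrichment against the pooled reference.

    For every pattern observed in a focal pool: FO in the pool, FO in the
    union of the remaining pools, FO in the remaining pools of the same
    strategy (GBSS); fold changes against both references (a zero-count
    reference FO is floored at 1/(reference total + 1) so absence elsewhere
    yields a large finite fold); one-sided Fisher p against the all-pools
    reference, BH-adjusted within the (pool, k) family; 50x/500x flags on
    the larger of the two folds.
    """
    if len(pools) < 2:
        raise PatternError("need at least 2 pools")
    counts = {label: count_kmers(p, k)[0] for label, p in pools.items()}
    totals = {label: sum(c.values()) for label, c in counts.items()}
    strategies = {label: p.strategy for label, p in pools.items()}

    rows: list[dict] = []
    for label, pool in pools.items():
        focal = counts[label]
        total_focal = totals[label]
        if total_focal == 0:
            continue
        others = [l for l in pools if l != label or include_focal_in_reference]
        ref_total = sum(totals[l] for l in others)
        gbss = [
            l for l in others
            if strategies[l] == strategies[label] and l != label
        ]
        gbss_total = sum(totals[l] for l in gbss)
        if ref_total == 0:
            raise PatternError(f"empty reference for pool {label!r}")
        patterns = sorted(focal)
        c_pool = np.array([focal[p] for p in patterns])
        c_ref = np.array([sum(counts[l].get(p, 0) for l in others) for p in patterns])
        c_gbss = np.array([sum(counts[l].get(p, 0) for l in gbss) for p in patterns])
        fo_pool = c_pool / total_focal
        floor_ref = 1.0 / (ref_total + 1)
        floor_gbss = 1.0 / (gbss_total + 1) if gbss_total else np.nan
        fo_ref = c_ref / ref_total
        fo_gbss = c_gbss / gbss_total if gbss_total else np.full(len(patterns), np.nan)
        fold_all = fo_pool / np.maximum(fo_ref, floor_ref)
        fold_gbss = (
            fo_pool / np.maximum(fo_gbss, floor_gbss)
            if gbss_total
            else np.full(len(patterns), np.nan)
        )
        pvals = _fisher_greater_pvalues(c_pool, total_focal, c_ref, ref_total)
        p_adj = multipletests(pvals, method="fdr_bh")[1] if len(pvals) else pvals
        best_fold = np.fmax(fold_all, fold_gbss)
        for idx, pat in enumerate(patterns):
            rows.append(
                {
                    "pool": label, "pattern": pat, "k": k,
                    "count": int(c_pool[idx]),
                    "fo_pool": fo_pool[idx],
                    "fo_remaining": fo_ref[idx],
                    "fo_remaining_gbss": fo_gbss[idx],
                    "fold_all": fold_all[idx],
                    "fold_gbss": fold_gbss[idx],
                    "p": pvals[idx],
                    "p_adj": p_adj[idx],
                    "flag50": bool(best_fold[idx] >= FLAG50_FOLD),
                    "flag500": bool(best_fold[idx] >= FLAG500_FOLD),
                    "significant": bool(p_adj[idx] < alpha),
                }
            )
    return pd.DataFrame(rows)


def pattern_stats(table: pd.DataFrame) -> list[PatternStat]:
    """Typed view of an enrichment table's rows."""
    return [
        PatternStat(
            pattern=r["pattern"], pool=r["pool"], count=int(r["count"]),
            fo_pool=r["fo_pool"], fo_remaining=r["fo_remaining"],
            fo_remaining_same_strategy=r["fo_remaining_gbss"],
            fold_all=r["fold_all"], fold_gbss=r["fold_gbss"],
            p=r["p"], p_adj=r["p_adj"],
            flag50=bool(r["flag50"]), flag500=bool(r["flag500"]),
        )
        for _, r in table.iterrows()
    ]
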