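"""k-mer counting, Markov background, coverage and enrichment statistics."""

import itertools

import numpy as np
import pytest
from scipy.stats import fisher_exact

from helpers import bh_adjust, fisher_greater_exhaustive
from hydrosep.patterns import (
    PatternError,
    _fisher_greater_pvalues,
    count_kmers,
    coverage_by_length,
    enrichment_table,
    fit_markov,
    pattern_stats,
)
from hydrosep.pools import PeptidePool, PeptideRecord
from hydrosep.synthetic import MotifPlant, SegmentPlan, SyntheticSpec, generate_proteins


def make_pool(seqs, label="x", strategy="structure"):
    recs = [
        PeptideRecord(f"{label}{i}", s, "C" * len(s), "S" * len(s))
        for i, s in enumerate(seqs)
    ]
    return PeptidePool(label=label, records=recs, strategy=strategy)


def random_pool(n, length, seed, label="x", strategy="structure", bias=None):
    rng = np.random.default_rng(seed)
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    p = np.ones(20) / 20 if bias is None else bias
    return make_pool(
        ["".join(rng.choice(aas, size=length, p=p)) for _ in range(n)],
        label=label, strategy=strategy,
    )


# ---------------------------------------------------------------------------
# counting

def test_count_kmers_examples():
    counts, fo = count_kmers(make_pool(["AAAA"]), 2)
    assert counts == {"AA": 3}
    assert fo == {"AA": 1.0}
    counts2, _ = count_kmers(make_pool(["AAAA", "AC"]), 3)
    assert counts2 == {"AAA": 2}  # the 2-mer peptide contributes nothing


def test_count_kmers_counting_identity():
    pool = random_pool(20, 15, seed=1)
    for k in (2, 3, 5):
        counts, fo = count_kmers(pool, k)
        assert sum(counts.values()) == sum(max(0, 15 - k + 1) for _ in range(20))
        assert sum(fo.values()) == pytest.approx(1.0, abs=1e-9)


def test_count_kmers_k_range_guard():
    with pytest.raises(PatternError):
        count_kmers(make_pool(["AAAA"]), 6)


# ---------------------------------------------------------------------------
# Markov background

def test_markov_degenerate_chain():
    model = fit_markov(make_pool(["A" * 2000]), order=1)
    assert model.transitions["A"]["A"] > 0.95
    assert model.pattern_probability("AA") == pytest.approx(
        model.initial["A"] * model.transitions["A"]["A"]
    )


def test_markov_order_zero_is_composition_product():
    pool = random_pool(10, 20, seed=2)
    model = fit_markov(pool, order=0)
    p = model.pattern_probability("ACD")
    assert p == pytest.approx(
        model.initial["A"] * model.initial["C"] * model.initial["D"]
    )


def test_markov_probabilities_sum_to_one_exhaustively():
    pool = random_pool(10, 25, seed=3)
    model = fit_markov(pool, order=1)
    total = sum(
        model.pattern_probability(a + b)
        for a, b in itertools.product("ACDEFGHIKLMNPQRSTVWY", repeat=2)
    )
    assert total == pytest.approx(1.0, abs=1e-6)


# ---------------------------------------------------------------------------
# coverage

def test_coverage_identical_pools_is_one():
    pool = random_pool(10, 20, seed=4)
    twin = make_pool([r.sequence for r in pool.records], label="y")
    cov = coverage_by_length({"a": pool, "b": twin})
    assert all(v == 1.0 for v in cov.values())


def test_coverage_excludes_private_patterns():
    a = make_pool(["ACACACACAC"], label="a")
    b = make_pool(["ACACACACAW"], label="b")  # AW only in b
    cov = coverage_by_length({"a": a, "b": b}, k_range=[2])
    # union {AC, CA, AW}, shared {AC, CA}
    assert cov[2] == pytest.approx(2 / 3)


def test_coverage_non_increasing_in_k_on_synthetic_pools():
    pools = {
        f"p{i}": random_pool(200, 20, seed=10 + i, label=f"p{i}") for i in range(4)
    }
    cov = coverage_by_length(pools)
    vals = [cov[k] for k in sorted(cov)]
    assert all(a >= b for a, b in zip(vals, vals[1:]))
    assert vals[0] > vals[-1]  # the trend is strict over the whole range


# ---------------------------------------------------------------------------
# Fisher / BH

def test_fisher_matches_exhaustive_oracle_small_margins():
    rng = np.random.default_rng(5)
    for _ in range(50):
        a = int(rng.integers(0, 20))
        b = int(rng.integers(0, 31))
        c = int(rng.integers(0, 20))
        d = int(rng.integers(0, 31))
        if (a + b) == 0 or (c + d) == 0:
            continue
        ours = float(_fisher_greater_pvalues(np.array([a]), a + b, np.array([c]), c + d)[0])
        oracle = fisher_greater_exhaustive(a, b, c, d)
        assert ours == pytest.approx(oracle, abs=1e-12)
        scipy_p = fisher_exact([[a, b], [c, d]], alternative="greater")[1]
        assert ours == pytest.approx(scipy_p, abs=1e-9)


def test_fisher_specific_table_matches_tail_sum():
    ours = float(_fisher_greater_pvalues(np.array([5]), 100, np.array([5]), 10_000)[0])
    assert ours == pytest.approx(fisher_greater_exhaustive(5, 95, 5, 9995), rel=1e-10)


def test_bh_reference_case():
    assert bh_adjust([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.03, 0.04])


def test_enrichment_p_adj_is_bh_within_family():
    pools = {
        "a": random_pool(30, 15, seed=6, label="a"),
        "b": random_pool(30, 15, seed=7, label="b"),
    }
    table = enrichment_table(pools, 2)
    for label, grp in table.groupby("pool"):
        assert grp["p_adj"].values == pytest.approx(
            bh_adjust(list(grp["p"].values)), abs=1e-9
        )


# ---------------------------------------------------------------------------
# enrichment semantics

def test_fold_flooring_for_absent_reference_pattern():
    focal = make_pool(["WWWWWWWWWW"] * 2, label="focal")
    rng = np.random.default_rng(8)
    ref = make_pool(  # reference alphabet excludes W entirely
        ["".join(rng.choice(list("ACDEGHKLNS"), size=20)) for _ in range(50)],
        label="ref",
    )
    table = enrichment_table({"focal": focal, "ref": ref}, 2)
    row = table[(table["pool"] == "focal") & (table["pattern"] == "WW")].iloc[0]
    ref_total = sum(count_kmers(ref, 2)[0].values())
    assert row["fo_remaining"] == 0.0
    assert row["fold_all"] == pytest.approx(row["fo_pool"] * (ref_total + 1))
    assert row["flag50"]


def test_gbss_reference_restricted_to_same_strategy():
    a = make_pool(["ACACACACAC"] * 5, label="a", strategy="structure")
    b = make_pool(["DEDEDEDEDE"] * 5, label="b", strategy="structure")
    c = make_pool(["ACDEACDEAC"] * 5, label="c", strategy="digest")
    table = enrichment_table({"a": a, "b": b, "c": c}, 2)
    row = table[(table["pool"] == "a") & (table["pattern"] == "AC")].iloc[0]
    # GBSS reference for pool a is pool b only (same strategy), where AC is absent
    assert row["fo_remaining_gbss"] == 0.0
    # the all-pools reference includes pool c, where AC occurs
    assert row["fo_remaining"] > 0.0


def test_planted_motif_recovered_with_flags_and_significance():
    spec = SyntheticSpec(
        seed=12, n_proteins=300,
        segment_plan=(SegmentPlan("s_helix", 12, 18),),
        motif_plants=(MotifPlant("EELKK", "s_helix", 0.5),),
    )
    recs, _ = generate_proteins(spec)
    planted = PeptidePool("planted", recs, strategy="structure")
    background = {
        f"bg{i}": random_pool(300, 15, seed=20 + i, label=f"bg{i}")
        for i in range(3)
    }
    table = enrichment_table({"planted": planted, **background}, 5)
    row = table[(table["pool"] == "planted") & (table["pattern"] == "EELKK")].iloc[0]
    assert row["flag50"]
    assert row["p_adj"] < 0.05
    stats = pattern_stats(table[table["pattern"] == "EELKK"])
    assert stats[0].flag50


def test_null_pools_rarely_reach_flag500():
    """Without planted signal, no 5-mer should show a 500-fold enrichment
    in the overwhelming majority of seeded replicates."""
    failures = 0
    n_seeds = 20
    for seed in range(n_seeds):
        pools = {
            f"p{i}": random_pool(100, 20, seed=1000 * seed + i, label=f"p{i}")
            for i in range(6)
        }
        table = enrichment_table(pools, 5)
        if bool(table["flag500"].any()):
            failures += 1
    assert failures <= max(1, int(0.05 * n_seeds))
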