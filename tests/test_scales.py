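"""Scale parsing, transforms, dissimilarity and UPGMA clustering."""

import math

import numpy as np
import pytest

from helpers import brute_force_upgma_cophenetic, tree_cophenetic
from hydrosep.scales import (
    AA_ALPHABETICAL,
    AAINDEX_ORDER,
    DegenerateScaleError,
    HydrophobicityScale,
    ScaleError,
    ScaleParseError,
    aa_difference_matrix,
    minmax_normalize,
    parse_scale_table,
    reverse_scale,
    scale_dissimilarity,
    upgma_cluster,
)


def make_scale(values, sid="s", category="experimental"):
    return HydrophobicityScale(sid, sid, category, dict(zip(AA_ALPHABETICAL, values)))


# ---------------------------------------------------------------------------
# parsing

def test_two_column_round_trip():
    lines = ["#id: T1", "#name: test scale"]
    lines += [f"{aa}\t{i + 1}" for i, aa in enumerate(AAINDEX_ORDER)]
    (s,) = parse_scale_table("\n".join(lines), "two_column")
    assert s.id == "T1"
    assert s.values["A"] == 1.0
    assert s.values["V"] == 20.0


def test_two_column_missing_residue_names_count():
    lines = ["#id: T1"] + [f"{aa}\t1.{i}" for i, aa in enumerate(AAINDEX_ORDER) if aa != "W"]
    with pytest.raises(ScaleParseError, match="19 of 20"):
        parse_scale_table("\n".join(lines), "two_column")


def test_two_column_non_numeric_and_duplicate_id():
    bad = "#id: T1\nA\tx\n"
    with pytest.raises(ScaleParseError, match="non-numeric"):
        parse_scale_table(bad, "two_column")
    dup = "\n".join(
        ["#id: T1"] + [f"{aa}\t{i}.5" for i, aa in enumerate(AAINDEX_ORDER)]
        + ["#id: T1"] + [f"{aa}\t{i}.25" for i, aa in enumerate(AAINDEX_ORDER)]
    )
    with pytest.raises(ScaleParseError, match="duplicate"):
        parse_scale_table(dup, "two_column")


def test_aaindex_block_positional_mapping():
    # hand-built AAindex entry; expected mapping hand-derived from the
    # canonical residue order of the I line
    nums = [round(0.1 * i - 1.0, 2) for i in range(20)]
    block = (
        "H TEST010101\n"
        "D A synthetic test entry\n"
        "I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V\n"
        "   " + "  ".join(str(v) for v in nums[:10]) + "\n"
        "   " + "  ".join(str(v) for v in nums[10:]) + "\n"
        "//\n"
    )
    (s,) = parse_scale_table(block, "aaindex_flat")
    for letter, expected in zip(AAINDEX_ORDER, nums):
        assert s.values[letter] == pytest.approx(expected)


def test_constant_scale_rejected():
    with pytest.raises(DegenerateScaleError):
        make_scale([1.0] * 20)


# ---------------------------------------------------------------------------
# transforms

def test_reverse_scale_is_sign_inversion_and_involution(kd):
    rev = reverse_scale(kd)
    assert rev.category == "inverted"
    assert rev.values["A"] == pytest.approx(-1.8)
    back = reverse_scale(rev)
    assert back.values == kd.values
    r = np.corrcoef(kd.as_vector(), rev.as_vector())[0, 1]
    assert r == pytest.approx(-1.0)


def test_minmax_normalize_affine_idempotent_and_rank_preserving(kd):
    s = make_scale([float(5 * i) for i in range(20)])
    n = minmax_normalize(s)
    assert n.values[AA_ALPHABETICAL[0]] == 0.0
    assert n.values[AA_ALPHABETICAL[1]] == pytest.approx(0.5 / 9.5)
    assert max(n.values.values()) == 1.0 and min(n.values.values()) == 0.0
    again = minmax_normalize(n)
    assert all(abs(again.values[a] - n.values[a]) < 1e-12 for a in AA_ALPHABETICAL)
    nk = minmax_normalize(kd)
    assert max(kd.values, key=kd.values.get) == max(nk.values, key=nk.values.get)
    assert min(kd.values, key=kd.values.get) == min(nk.values, key=nk.values.get)


# ---------------------------------------------------------------------------
# dissimilarity

def test_dissimilarity_identities(kd, scales_by_id):
    assert scale_dissimilarity(kd, kd) == 0.0
    assert scale_dissimilarity(kd, reverse_scale(kd)) == pytest.approx(0.0, abs=1e-12)
    for a in scales_by_id.values():
        for b in scales_by_id.values():
            assert scale_dissimilarity(a, b) == pytest.approx(
                scale_dissimilarity(b, a), abs=1e-12
            )


def test_dissimilarity_closed_form_r06():
    # construct two vectors with Pearson correlation exactly 0.6
    rng = np.random.default_rng(0)
    x = rng.normal(size=20)
    z = rng.normal(size=20)
    xh = (x - x.mean()) / x.std()
    z = z - z.mean()
    z -= (z @ xh) / (xh @ xh) * xh
    zh = z / z.std()
    y = 0.6 * xh + 0.8 * zh
    d = scale_dissimilarity(make_scale(xh, "a"), make_scale(y, "b"))
    assert d == pytest.approx(0.8, abs=1e-9)


# ---------------------------------------------------------------------------
# UPGMA

def _three_leaf_scales():
    rng = np.random.default_rng(1)
    return [make_scale(rng.normal(size=20), sid) for sid in "ABC"]


def test_upgma_three_leaf_hand_case():
    d = np.array([[0.0, 0.2, 0.6], [0.2, 0.0, 0.6], [0.6, 0.6, 0.0]])
    scales = _three_leaf_scales()
    low = upgma_cluster(scales, threshold=0.05, dissimilarity=d)
    assert len(set(low.clusters.values())) == 3  # all singletons
    hi = upgma_cluster(scales, threshold=0.25, dissimilarity=d)
    assert hi.clusters["A"] == hi.clusters["B"] != hi.clusters["C"]
    coph = tree_cophenetic(hi.tree, ["A", "B", "C"])
    assert coph[0, 1] == pytest.approx(0.1)
    assert coph[0, 2] == pytest.approx(0.3)


def test_scale_and_reverse_always_co_cluster(scales_by_id):
    scales = list(scales_by_id.values()) + [reverse_scale(scales_by_id["KD"])]
    clustering = upgma_cluster(scales, threshold=0.01)
    assert clustering.clusters["KD"] == clustering.clusters["KD_rev"]


@pytest.mark.parametrize("seed", range(10))
def test_upgma_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 9))
    d = rng.uniform(0.05, 1.0, size=(n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    ids = [f"s{i}" for i in range(n)]
    scales = [make_scale(np.random.default_rng(100 + i).normal(size=20), sid)
              for i, sid in enumerate(ids)]
    clustering = upgma_cluster(scales, threshold=0.1, dissimilarity=d)
    got = tree_cophenetic(clustering.tree, ids)
    expected = brute_force_upgma_cophenetic(d)
    assert np.allclose(got, expected, atol=1e-10)


def test_upgma_matrix_invariants_and_tree_is_ultrametric(scales_by_id):
    clustering = upgma_cluster(list(scales_by_id.values()), threshold=0.05)
    d = clustering.dissimilarity
    assert np.allclose(d, d.T)
    assert np.allclose(np.diag(d), 0.0)
    assert ((d >= 0) & (d <= 1)).all()

    def check(node):
        for c in node.children:
            assert c.height <= node.height + 1e-12
            check(c)

    check(clustering.tree)


def test_newick_output_parses_with_skbio(scales_by_id):
    import io

    import skbio

    clustering = upgma_cluster(list(scales_by_id.values()), threshold=0.05)
    tree = skbio.TreeNode.read(io.StringIO(clustering.to_newick()))
    assert sorted(t.name for t in tree.tips()) == sorted(scales_by_id)


def test_upgma_needs_two_scales(kd):
    with pytest.raises(ScaleError):
        upgma_cluster([kd], threshold=0.05)


# ---------------------------------------------------------------------------
# amino-acid distance analysis

def test_aa_difference_matrix_flags_and_symmetry(kd):
    m, similar, distant = aa_difference_matrix(kd)
    assert np.allclose(m, m.T)
    assert np.allclose(np.diag(m), 0.0)
    amax = max(kd.values, key=kd.values.get)
    amin = min(kd.values, key=kd.values.get)
    pair = tuple(sorted((amin, amax)))
    assert pair in distant
    i = AA_ALPHABETICAL.index(amin)
    j = AA_ALPHABETICAL.index(amax)
    assert m[i, j] == pytest.approx(1.0)
    # equal normalized values are flagged similar (distance 0 < low)
    assert all(m[i, j] < 0.1 for (a, b) in similar
               for i, j in [(AA_ALPHABETICAL.index(a), AA_ALPHABETICAL.index(b))])
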