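"""Hulls, overlap estimation, envelope stripping and the separation score."""

import math

import numpy as np
import pytest

from helpers import convex_hull_2d, polygon_area
from hydrosep.geometry import (
    Cloud,
    build_hull,
    formula_scores,
    overlap,
    separation_score,
    strip_envelope,
)

SQUARE = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


# ---------------------------------------------------------------------------
# hull construction

def test_unit_triangle():
    c = build_hull(np.array([[0, 0], [1, 0], [0, 1]], float))
    assert c.volume == pytest.approx(0.5)
    assert c.boundary_idx == {0, 1, 2}


@pytest.mark.parametrize("d", [2, 3, 4, 5])
def test_simplex_volume_is_inverse_factorial(d):
    pts = np.vstack([np.zeros(d), np.eye(d)])
    assert build_hull(pts).volume == pytest.approx(1 / math.factorial(d), abs=1e-9)


def test_interior_points_do_not_change_hull():
    rng = np.random.default_rng(0)
    interior = rng.uniform(0.05, 0.95, size=(100, 2))
    pts = np.vstack([SQUARE, interior])
    c = build_hull(pts)
    assert c.volume == pytest.approx(1.0, abs=1e-12)
    assert c.boundary_idx == {0, 1, 2, 3}
    # brute-force 2-D oracle agrees
    hull_idx = convex_hull_2d(pts)
    assert set(hull_idx) == c.boundary_idx
    assert polygon_area(pts[hull_idx]) == pytest.approx(c.volume)


def test_hull_volume_invariances():
    rng = np.random.default_rng(1)
    pts = rng.normal(size=(40, 3))
    v0 = build_hull(pts).volume
    # permutation
    for seed in range(10):
        perm = np.random.default_rng(seed).permutation(len(pts))
        c = build_hull(pts[perm])
        assert c.volume == pytest.approx(v0, rel=1e-9)
        assert {tuple(pts[perm][i]) for i in c.boundary_idx} == \
               {tuple(pts[i]) for i in build_hull(pts).boundary_idx}
    # translation
    assert build_hull(pts + 13.7).volume == pytest.approx(v0, rel=1e-9)
    # rotation
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    assert build_hull(pts @ q).volume == pytest.approx(v0, rel=1e-9)


def test_degenerate_input_flagged_not_crashed():
    line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
    c = build_hull(line)
    assert c.degenerate and c.volume == 0.0
    assert c.contains([1.5, 0, 0])
    assert not c.contains([1.5, 0.2, 0])
    assert not c.contains([9.0, 0, 0])


# ---------------------------------------------------------------------------
# membership

def test_contains_vertex_centroid_and_far_point():
    c = build_hull(SQUARE)
    assert c.contains([0.0, 0.0])          # vertex: boundary-inclusive
    assert c.contains([0.5, 0.5])          # centroid
    assert not c.contains([3.0, 3.0])      # far outside


# ---------------------------------------------------------------------------
# overlap

def test_identical_clouds_full_overlap():
    a = build_hull(SQUARE)
    b = build_hull(SQUARE.copy())
    ov = overlap(a, b, method="exact")
    assert ov.vov == pytest.approx(a.volume)
    assert ov.pov == a.n_points + b.n_points


def test_offset_squares_analytic_intersection():
    a = build_hull(SQUARE)
    b = build_hull(SQUARE + [0.5, 0.0])
    ov = overlap(a, b, method="exact")
    assert ov.vov == pytest.approx(0.5, abs=1e-9)
    assert ov.pov == 4
    mc = overlap(a, b, method="mc", mc_samples=50_000, seed=1)
    assert abs(mc.vov - 0.5) <= 3 * mc.mc_se


def test_disjoint_clouds():
    a = build_hull(SQUARE)
    b = build_hull(SQUARE + [5.0, 0.0])
    ov = overlap(a, b, method="exact")
    assert ov.vov == 0.0 and ov.pov == 0
    mc = overlap(a, b, method="mc", mc_samples=5000, seed=2)
    assert mc.vov == 0.0


@pytest.mark.parametrize("dim", [2, 3])
def test_mc_overlap_matches_exact_oracle(dim):
    """Monte-Carlo Vov within 3 standard errors of the half-space
    intersection on seeded random polytope pairs."""
    rng = np.random.default_rng(42)
    for trial in range(10):
        a = build_hull(rng.normal(size=(20, dim)))
        b = build_hull(rng.normal(size=(20, dim)) + 0.4)
        exact = overlap(a, b, method="exact").vov
        mc = overlap(a, b, method="mc", mc_samples=40_000, seed=trial)
        se = max(mc.mc_se, 1e-12)
        assert abs(mc.vov - exact) <= 3 * se + 1e-9


def test_small_sample_mc_records_warning():
    a = build_hull(SQUARE)
    b = build_hull(SQUARE + 0.2)
    mc = overlap(a, b, method="mc", mc_samples=500, seed=0)
    assert any("500" in w for w in mc.warnings)


# ---------------------------------------------------------------------------
# envelope stripping

def test_strip_square_with_single_interior_point():
    pts = np.vstack([SQUARE, [[0.5, 0.5]]])
    cloud = build_hull(pts)
    stripped, stats = strip_envelope(cloud)
    assert stats.n_removed == 4
    assert stats.frac_points_removed == pytest.approx(0.8)
    assert stripped.volume == 0.0
    assert stripped.n_points == 1


def test_strip_never_increases_volume():
    rng = np.random.default_rng(5)
    for _ in range(5):
        cloud = build_hull(rng.normal(size=(60, 3)))
        stripped, stats = strip_envelope(cloud)
        assert stripped.volume <= cloud.volume + 1e-12
        assert 0.0 <= stats.frac_volume_lost <= 1.0


def test_dense_gaussian_loses_more_volume_than_points():
    rng = np.random.default_rng(7)
    cloud = build_hull(rng.normal(size=(500, 3)))
    _, stats = strip_envelope(cloud)
    assert stats.frac_points_removed < stats.frac_volume_lost


# ---------------------------------------------------------------------------
# the separation score

def test_formula_arithmetic_cases():
    sv, sp, s = formula_scores(1.0, 1.0, 0.5, 10, 10, 5)
    assert (sv, sp, s) == pytest.approx((0.5, 0.75, 0.375), abs=1e-12)
    sv, sp, s = formula_scores(2.0, 4.0, 1.0, 7, 13, 0)
    assert sv == pytest.approx(1 - 2 / 6, abs=1e-12)
    assert sp == 1.0
    assert s == pytest.approx(sv, abs=1e-12)


def test_identical_point_sets_score_zero():
    a = build_hull(SQUARE)
    b = build_hull(SQUARE.copy())
    res = separation_score(a, b, method="mc", mc_samples=5000, seed=3)
    assert res.S == 0.0 and res.Sv == 0.0 and res.Sp == 0.0


def test_disjoint_clouds_score_one():
    a = build_hull(SQUARE)
    b = build_hull(SQUARE + [10.0, 0.0])
    res = separation_score(a, b, method="exact")
    assert res.S == 1.0 and res.Sv == 1.0 and res.Sp == 1.0


def test_score_monotone_under_translation():
    rng = np.random.default_rng(11)
    base = rng.uniform(size=(30, 2))
    a = build_hull(base)
    last = -1.0
    for shift in np.linspace(0.0, 2.5, 8):
        b = build_hull(base + [shift, 0.0])
        res = separation_score(a, b, method="exact")
        assert res.S >= last - 1e-9
        last = res.S
    assert last == 1.0


def test_degenerate_clouds_never_crash_scoring():
    line_a = build_hull(np.array([[0, 0], [1, 0], [2, 0]], float))
    line_b = build_hull(np.array([[0, 1], [1, 1], [2, 1]], float))
    res = separation_score(line_a, line_b, method="exact")
    assert res.S == 1.0  # disjoint affine supports
    res2 = separation_score(line_a, build_hull(np.array([[0, 0], [1, 0], [2, 0]], float)))
    assert res2.S == 0.0  # coincident supports, all points mutual


def test_separation_result_invariants():
    rng = np.random.default_rng(13)
    a = build_hull(rng.normal(size=(25, 3)))
    b = build_hull(rng.normal(size=(25, 3)) + 0.3)
    res = separation_score(a, b, method="exact")
    assert res.Vov <= min(res.V1, res.V2) + 1e-9
    assert res.Pov <= res.P1 + res.P2
    assert 0.0 <= res.S <= 1.0
    assert res.S == pytest.approx(res.Sv * res.Sp, abs=1e-12)
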