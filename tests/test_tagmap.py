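"""Occupancy-track construction, windowing, blurring, profiles, and
difference maps, checked against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import nucblur as nb
from nucblur.tagmap import _sliding_mean

from conftest import make_sites


def brute_force_coverage(starts, length, tag_length=146):
    track = np.zeros(length)
    for s in starts:
        for b in range(s, min(s + tag_length, length)):
            track[b] += 1
    return track


class TestCoverage:
    def test_single_tag(self):
        tm = nb.coverage_from_tags({"c1": [10]}, {"c1": 1000})
        arr = tm["c1"]
        assert arr[9] == 0 and arr[10] == 1 and arr[155] == 1 and arr[156] == 0
        assert arr.sum() == 146

    def test_overlapping_tags_stack(self):
        tm = nb.coverage_from_tags({"c1": [10, 100]}, {"c1": 1000})
        assert (tm["c1"][100:156] == 2).all()

    def test_matches_brute_force(self, rng):
        length = 800
        starts = rng.integers(0, length, size=200)
        tm = nb.coverage_from_tags({"c1": starts}, {"c1": length})
        assert np.array_equal(tm["c1"], brute_force_coverage(starts, length))

    def test_mass_conservation_with_truncation(self, rng):
        length = 500
        starts = rng.integers(0, length, size=60)
        truncated = np.maximum(starts + 146 - length, 0).sum()
        tm = nb.coverage_from_tags({"c1": starts}, {"c1": length})
        assert tm.total() == 146 * len(starts) - truncated

    def test_out_of_bounds_start_rejected(self):
        with pytest.raises(nb.BoundsError):
            nb.coverage_from_tags({"c1": [1000]}, {"c1": 1000})
        with pytest.raises(nb.BoundsError):
            nb.coverage_from_tags({"c1": [-1]}, {"c1": 1000})


class TestNormalize:
    def test_constant_track(self):
        tm = nb.TagMap({"c1": np.full(100, 5.0)})
        assert np.allclose(nb.normalize_mean1(tm)["c1"], 1.0)

    def test_idempotent_and_mean_one(self, rng):
        tm = nb.TagMap({"c1": rng.poisson(7, 300).astype(float),
                        "c2": rng.poisson(3, 200).astype(float)})
        once = nb.normalize_mean1(tm)
        assert abs(once.mean() - 1.0) < 1e-12
        twice = nb.normalize_mean1(once)
        for name in tm.names:
            assert np.allclose(once[name], twice[name], atol=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(nb.DegenerateInputError):
            nb.normalize_mean1(nb.TagMap({"c1": np.zeros(10)}))


class TestWindowAverage:
    def test_constant_track_any_window(self):
        tm = nb.TagMap({"c1": np.full(500, 3.5)})
        for size in nb.BLUR_WINDOW_SIZES:
            assert nb.window_average(tm, "c1", 250, size) == 3.5

    def test_delta_track(self):
        tm = nb.TagMap({"c1": np.array([0.0, 0, 10, 0, 0])})
        assert nb.window_average(tm, "c1", 2, 5) == 2.0

    def test_even_motif_extends_right(self):
        tm = nb.TagMap({"c1": np.arange(20, dtype=float)})
        odd = nb.window_average(tm, "c1", 10, 4, motif_even=False)
        even = nb.window_average(tm, "c1", 10, 4, motif_even=True)
        # odd: bp 8..11 inclusive; even motif adds bp 12
        assert odd == np.mean([8, 9, 10, 11])
        assert even == np.mean([8, 9, 10, 11, 12])

    def test_matches_naive_loop(self, rng):
        arr = rng.poisson(5, 3000).astype(float)
        tm = nb.TagMap({"c1": arr})
        for _ in range(100):
            c = int(rng.integers(0, 3000))
            size = int(rng.choice(nb.BLUR_WINDOW_SIZES))
            start = c - size // 2
            expected = arr[max(start, 0): min(start + size, 3000)].mean()
            assert nb.window_average(tm, "c1", c, size) == pytest.approx(
                expected, abs=1e-12)

    def test_fully_off_chromosome_rejected(self):
        tm = nb.TagMap({"c1": np.ones(100)})
        with pytest.raises(nb.BoundsError):
            nb.window_average(tm, "c1", -60, 15)


class TestBlur:
    def test_window_one_is_identity(self, rng):
        arr = rng.poisson(4, 200).astype(float)
        tm = nb.TagMap({"c1": arr})
        assert np.array_equal(nb.blur(tm, 1)["c1"], arr)

    def test_constant_unchanged(self):
        tm = nb.TagMap({"c1": np.full(400, 2.0)})
        for w in (15, 40, 600):
            assert np.allclose(nb.blur(tm, w)["c1"], 2.0)

    def test_delta_becomes_plateau(self):
        arr = np.zeros(301)
        arr[150] = 1.0
        blurred = nb.blur(nb.TagMap({"c1": arr}), 75)["c1"]
        plateau = blurred[blurred > 0]
        assert plateau.size == 75
        assert np.allclose(plateau, 1.0 / 75)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(min_value=1, max_value=50), st.integers(0, 2 ** 31 - 1))
    def test_linear_operator(self, w, seed):
        r = np.random.default_rng(seed)
        a, b = r.random(120), r.random(120)
        blur_a = _sliding_mean(a, w)
        blur_b = _sliding_mean(b, w)
        assert np.allclose(_sliding_mean(a + b, w), blur_a + blur_b,
                           atol=1e-9)
        assert np.allclose(_sliding_mean(3.0 * a, w), 3.0 * blur_a,
                           atol=1e-9)

    def test_consistent_with_window_average_interior(self, rng):
        arr = rng.poisson(6, 2000).astype(float)
        tm = nb.TagMap({"c1": arr})
        for w in (15, 40, 75, 150):
            blurred = nb.blur(tm, w)
            for c in (700, 1000, 1300):
                assert blurred["c1"][c] == pytest.approx(
                    nb.window_average(tm, "c1", c, w), abs=1e-9)

    def test_mean_roughly_preserved(self, rng):
        arr = rng.poisson(10, 50_000).astype(float)
        tm = nb.TagMap({"c1": arr})
        blurred = nb.blur(tm, 600)
        assert blurred.mean() == pytest.approx(tm.mean(), rel=1e-3)


class TestExtractProfile:
    def test_delta_at_center(self):
        arr = np.zeros(2001)
        arr[1000] = 7.0
        sites = make_sites([("A", "c1", 998, 1003, "+", 1e-4)])
        prof = nb.extract_profile(nb.TagMap({"c1": arr}), sites,
                                  half_width=600)
        assert prof.values[prof.half_width] == 7.0
        assert prof.values.sum() == 7.0

    def test_symmetrized_equals_own_mirror(self, rng):
        arr = rng.poisson(5, 3000).astype(float)
        sites = make_sites([("A", "c1", 1500, 1507, "+", 1e-4)])
        prof = nb.extract_profile(nb.TagMap({"c1": arr}), sites,
                                  half_width=300, symmetrize=True)
        assert np.array_equal(prof.values, prof.values[::-1])

    def test_two_sites_mean_matches_hand_average(self, rng):
        arr = rng.poisson(5, 4000).astype(float)
        tm = nb.TagMap({"c1": arr})
        sites = make_sites([
            ("A", "c1", 1000, 1005, "+", 1e-4),
            ("A", "c1", 2500, 2505, "+", 1e-4),
        ])
        h = 200
        prof = nb.extract_profile(tm, sites, half_width=h)
        c1, c2 = 1002, 2502
        expected = 0.5 * (arr[c1 - h: c1 + h + 1] + arr[c2 - h: c2 + h + 1])
        assert np.allclose(prof.values, expected)

    def test_minus_strand_is_reversed(self):
        arr = np.zeros(2001, dtype=float)
        arr[1010] = 1.0  # 8 bp downstream (genome direction) of center 1002
        tm = nb.TagMap({"c1": arr})
        plus = nb.extract_profile(
            tm, make_sites([("A", "c1", 1000, 1005, "+", 1e-4)]), half_width=20)
        minus = nb.extract_profile(
            tm, make_sites([("A", "c1", 1000, 1005, "-", 1e-4)]), half_width=20)
        h = 20
        assert plus.values[h + 8] == 1.0
        assert minus.values[h - 8] == 1.0

    def test_clipped_sites_dropped(self):
        tm = nb.TagMap({"c1": np.ones(1000)})
        sites = make_sites([
            ("A", "c1", 10, 15, "+", 1e-4),     # window clipped at start
            ("A", "c1", 500, 505, "+", 1e-4),
        ])
        prof = nb.extract_profile(tm, sites, half_width=300)
        assert prof.n_sites == 1 and prof.n_dropped == 1
        with pytest.raises(nb.DegenerateInputError):
            nb.extract_profile(tm, sites.iloc[:1], half_width=600)


class TestScaleToReference:
    def test_double_map_halves(self, rng):
        ref = nb.TagMap({"c1": rng.poisson(5, 500).astype(float)})
        doubled = nb.TagMap({"c1": 2.0 * ref["c1"]})
        scaled = nb.scale_to_reference(doubled, ref)
        assert np.allclose(scaled["c1"], ref["c1"])

    def test_ratios_preserved(self, rng):
        tm = nb.TagMap({"c1": rng.poisson(5, 500).astype(float) + 1})
        ref = nb.TagMap({"c1": rng.poisson(9, 500).astype(float)})
        scaled = nb.scale_to_reference(tm, ref)
        assert np.allclose(scaled["c1"] / tm["c1"],
                           scaled["c1"][0] / tm["c1"][0])

    def test_flank_mode_matches_flanks_only(self):
        # two-region construction: identical flanks, different site-proximal
        arr_ref = np.full(3001, 10.0)
        arr_map = np.full(3001, 20.0)
        arr_ref[1420:1581] = 2.0    # site-proximal occupancy differs
        arr_map[1420:1581] = 30.0
        ref = nb.TagMap({"c1": arr_ref})
        tm = nb.TagMap({"c1": arr_map})
        sites = make_sites([("A", "c1", 1498, 1503, "+", 1e-4)])
        scaled = nb.scale_to_reference(tm, ref, mode="flank", sites=sites)
        # flanks (100-600 bp away) now agree ...
        assert scaled["c1"][1700] == pytest.approx(10.0)
        # ... but the site-proximal contrast is preserved (30/20 of flank)
        assert scaled["c1"][1500] == pytest.approx(15.0)

    def test_zero_reference_mass_rejected(self):
        tm = nb.TagMap({"c1": np.zeros(100)})
        ref = nb.TagMap({"c1": np.ones(100)})
        with pytest.raises(nb.DegenerateInputError):
            nb.scale_to_reference(tm, ref)


class TestDifferenceMap:
    def test_identical_maps_give_zero(self, rng):
        arr = rng.poisson(8, 1000).astype(float)
        tm = nb.TagMap({"c1": arr})
        diff = nb.difference_map(tm, tm.copy())
        assert np.allclose(diff["c1"], 0.0, atol=1e-9)

    def test_sums_to_zero(self, rng):
        x = nb.TagMap({"c1": rng.poisson(12, 2000).astype(float)})
        u = nb.TagMap({"c1": rng.poisson(10, 2000).astype(float)})
        diff = nb.difference_map(x, u)
        assert abs(diff.total()) < 1e-6 * x.mean() * 2000

    def test_planted_excess_recovered(self):
        n = 20_000
        u = np.full(n, 10.0)
        x = u.copy()
        e = 5.0
        x[5000:5146] += e
        diff = nb.difference_map(nb.TagMap({"c1": x}), nb.TagMap({"c1": u}))
        # scaling factor for the uncrosslinked map
        s = x.sum() / u.sum()
        expected_on = 10.0 + e - 10.0 * s
        expected_off = 10.0 - 10.0 * s
        assert np.allclose(diff["c1"][5000:5146], expected_on, atol=1e-9)
        assert np.allclose(diff["c1"][0:5000], expected_off, atol=1e-9)
        assert expected_off < 0 < expected_on

    def test_mismatched_genomes_rejected(self):
        x = nb.TagMap({"c1": np.ones(10)})
        u = nb.TagMap({"c1": np.ones(12)})
        with pytest.raises(nb.ShapeError):
            nb.difference_map(x, u)


def test_strand_balanced_profile_is_symmetric():
    """A strand-symmetric track profiled over +/- site pairs at the same
    locus is mirror-symmetric without explicit symmetrization."""
    arr = np.zeros(2001)
    arr[1010] = 1.0
    tm = nb.TagMap({"c1": arr})
    sites = make_sites([
        ("A", "c1", 1000, 1005, "+", 1e-4),
        ("A", "c1", 1000, 1005, "-", 1e-4),
    ])
    prof = nb.extract_profile(tm, sites, half_width=50, symmetrize=False)
    assert np.array_equal(prof.values, prof.values[::-1])
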