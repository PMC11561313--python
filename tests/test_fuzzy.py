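"""Favourability transform and fuzzy-set comparison of membership surfaces."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.special import expit, logit

from fuzzysdm import MembershipSurface
from fuzzysdm.fuzzy import (
    favourability,
    favourability_surface,
    fuzzy_entropy,
    fuzzy_intersection,
    fuzzy_overlap_index,
    fuzzy_union,
    shared_favourability_profile,
    similarity_matrix,
)
from conftest import random_surface


# -- independent brute-force oracles ---------------------------------------

def brute_fovi(a, b):
    num = den = 0.0
    for x, y in zip(a.ravel(), b.ravel()):
        num += min(x, y)
        den += max(x, y)
    return num / den


def brute_entropy(a):
    num = den = 0.0
    for x in a.ravel():
        num += min(x, 1 - x)
        den += max(x, 1 - x)
    return num / den


def brute_binary_jaccard(a, b, thr=0.5):
    sa = {i for i, x in enumerate(a.ravel()) if x >= thr}
    sb = {i for i, x in enumerate(b.ravel()) if x >= thr}
    union = sa | sb
    return len(sa & sb) / len(union) if union else 0.0


class TestFavourability:
    def test_prevalence_maps_to_half(self):
        n1, n0 = 30, 120
        assert favourability(n1 / (n1 + n0), n1, n0) == pytest.approx(0.5, abs=1e-12)

    def test_balanced_design_is_identity(self):
        p = np.linspace(0, 1, 21)
        np.testing.assert_allclose(favourability(p, 50, 50), p, atol=1e-12)

    def test_odds_form_value(self):
        assert favourability(0.8, 50, 100) == pytest.approx(4 / 4.5, abs=1e-9)
        assert favourability(0.8, 50, 100) == pytest.approx(0.8889, abs=1e-4)

    def test_limits(self):
        assert favourability(0.0, 10, 90) == 0.0
        assert favourability(1.0, 10, 90) == 1.0

    def test_zero_counts_rejected(self):
        with pytest.raises(ValueError, match="prevalence"):
            favourability(0.5, 0, 10)
        with pytest.raises(ValueError, match="prevalence"):
            favourability(0.5, 10, 0)

    @given(p=st.floats(0.001, 0.999), n1=st.integers(1, 500), n0=st.integers(1, 500))
    @settings(max_examples=200, deadline=None)
    def test_intercept_shift_identity(self, p, n1, n0):
        # odds form == logistic with the intercept shifted by -ln(n1/n0)
        shifted = expit(logit(p) - np.log(n1 / n0))
        assert favourability(p, n1, n0) == pytest.approx(shifted, abs=1e-12)

    @given(n1=st.integers(1, 200), n0=st.integers(1, 200))
    @settings(max_examples=50, deadline=None)
    def test_strictly_monotone_in_p(self, n1, n0):
        p = np.linspace(0.001, 0.999, 50)
        f = favourability(p, n1, n0)
        assert np.all(np.diff(f) > 0)


class TestFavourabilitySurface:
    def test_constant_prevalence_surface(self):
        surf = MembershipSurface(values=np.full((3, 3), 0.2), kind="probability")
        out = favourability_surface(surf, 20, 80)
        np.testing.assert_allclose(out.values, 0.5, atol=1e-12)
        assert out.kind == "favourability"
        assert out.provenance["n1"] == 20

    def test_relative_suitability_rejected(self):
        surf = MembershipSurface(values=np.full((2, 2), 0.4), kind="relative_suitability")
        with pytest.raises(ValueError, match="relative-suitability"):
            favourability_surface(surf, 10, 10)

    def test_elementwise_agreement_with_scalar(self):
        rng = np.random.default_rng(0)
        surf = MembershipSurface(values=rng.random((4, 4)), kind="probability")
        out = favourability_surface(surf, 13, 77)
        for r, c in [(0, 0), (1, 3), (2, 2), (3, 1), (3, 3)]:
            assert out.values[r, c] == pytest.approx(
                favourability(surf.values[r, c], 13, 77), abs=1e-12)

    def test_nodata_propagates(self):
        vals = np.array([[0.2, np.nan], [0.8, 0.5]])
        out = favourability_surface(
            MembershipSurface(values=vals, kind="probability"), 10, 10)
        assert np.isnan(out.values[0, 1])


class TestFuzzySetOps:
    def test_intersection_idempotent_absorbing_elementwise(self):
        a = MembershipSurface(values=np.array([[0.2, 0.9]]), kind="favourability")
        b = MembershipSurface(values=np.array([[0.7, 0.4]]), kind="favourability")
        zero = MembershipSurface(values=np.zeros((1, 2)), kind="favourability")
        np.testing.assert_array_equal(fuzzy_intersection(a, a).values, a.values)
        np.testing.assert_array_equal(fuzzy_intersection(a, zero).values, 0.0)
        np.testing.assert_array_equal(fuzzy_intersection(a, b).values, [[0.2, 0.4]])
        np.testing.assert_array_equal(fuzzy_union(a, b).values, [[0.7, 0.9]])

    def test_union_dominates_intersection(self):
        rng = np.random.default_rng(1)
        a, b = random_surface(rng), random_surface(rng)
        assert np.all(fuzzy_union(a, b).values >= fuzzy_intersection(a, b).values)

    def test_footprint_mismatch_rejected(self):
        a = MembershipSurface(values=np.zeros((2, 2)), kind="favourability")
        b = MembershipSurface(values=np.zeros((3, 2)), kind="favourability")
        with pytest.raises(ValueError, match="shape"):
            fuzzy_intersection(a, b)


class TestFuzzyOverlapIndex:
    def test_identical_and_disjoint(self):
        rng = np.random.default_rng(2)
        a = random_surface(rng)
        assert fuzzy_overlap_index(a, a) == pytest.approx(1.0)
        left = MembershipSurface(values=np.array([[0.8, 0.0]]), kind="favourability")
        right = MembershipSurface(values=np.array([[0.0, 0.6]]), kind="favourability")
        assert fuzzy_overlap_index(left, right) == 0.0

    def test_two_cell_hand_value(self):
        a = MembershipSurface(values=np.array([[0.2, 0.9]]), kind="favourability")
        b = MembershipSurface(values=np.array([[0.7, 0.4]]), kind="favourability")
        assert fuzzy_overlap_index(a, b) == pytest.approx(0.375)

    def test_both_zero_rejected(self):
        z = MembershipSurface(values=np.zeros((2, 2)), kind="favourability")
        with pytest.raises(ValueError, match="identically zero"):
            fuzzy_overlap_index(z, z)

    def test_axioms_on_random_surfaces(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a, b = random_surface(rng), random_surface(rng)
            f = fuzzy_overlap_index(a, b)
            assert 0.0 <= f <= 1.0
            assert f == pytest.approx(fuzzy_overlap_index(b, a))
            assert f == pytest.approx(brute_fovi(a.values, b.values))
            c = rng.uniform(0.1, 1.0)
            sa = MembershipSurface(values=a.values * c, kind="favourability")
            sb = MembershipSurface(values=b.values * c, kind="favourability")
            assert fuzzy_overlap_index(sa, sb) == pytest.approx(f)


class TestSimilarityMatrix:
    def test_diagonal_symmetry(self):
        rng = np.random.default_rng(4)
        surfs = [random_surface(rng) for _ in range(3)]
        for mode in ("fuzzy", "binary"):
            m = similarity_matrix(surfs, mode=mode)
            np.testing.assert_allclose(np.diag(m.values), 1.0)
            np.testing.assert_allclose(m.values, m.values.T)

    def test_crisp_surfaces_fuzzy_equals_binary(self):
        rng = np.random.default_rng(5)
        surfs = [MembershipSurface(values=(rng.random((4, 4)) > 0.5).astype(float),
                                   kind="favourability") for _ in range(2)]
        f = similarity_matrix(surfs, mode="fuzzy")
        b = similarity_matrix(surfs, mode="binary")
        np.testing.assert_array_equal(f.values, b.values)

    def test_binary_counting_example(self):
        # |A|=4, |B|=3, |A and B|=2 -> J = 2/5
        a = np.zeros((1, 6)); a[0, :4] = 1.0
        b = np.zeros((1, 6)); b[0, 2:5] = 1.0
        m = similarity_matrix(
            [MembershipSurface(values=a, kind="favourability"),
             MembershipSurface(values=b, kind="favourability")], mode="binary")
        assert m.values[0, 1] == pytest.approx(0.4)
        assert m.values[0, 1] == pytest.approx(brute_binary_jaccard(a, b))


class TestSharedFavourabilityProfile:
    def test_constant_surfaces_single_bin(self):
        a = MembershipSurface(values=np.full((3, 4), 0.6), kind="favourability")
        b = MembershipSurface(values=np.full((3, 4), 0.3), kind="favourability")
        prof = shared_favourability_profile(a, b)
        t = prof.table
        assert t.loc[3, "n_cells"] == 12  # overlap 0.3 lives in [0.3, 0.4)
        assert t.loc[3, "mean_F_A"] == pytest.approx(0.6)
        assert t.loc[3, "mean_F_B"] == pytest.approx(0.3)
        assert t.loc[3, "ci_A_high"] - t.loc[3, "ci_A_low"] == pytest.approx(0.0)
        assert t.drop(3)["n_cells"].sum() == 0

    def test_identical_surfaces_bin_means(self):
        rng = np.random.default_rng(6)
        a = random_surface(rng, shape=(6, 6))
        prof = shared_favourability_profile(a, a)
        vals = a.values.ravel()
        idx = np.minimum((vals * 10).astype(int), 9)
        for b in range(10):
            sel = vals[idx == b]
            if len(sel):
                assert prof.table.loc[b, "mean_F_A"] == pytest.approx(sel.mean())
                assert prof.table.loc[b, "mean_F_A"] == prof.table.loc[b, "mean_F_B"]

    def test_brute_force_binning_and_t_intervals(self):
        rng = np.random.default_rng(7)
        a, b = random_surface(rng, shape=(2, 3)), random_surface(rng, shape=(2, 3))
        prof = shared_favourability_profile(a, b, n_bins=10, confidence=0.95)
        overlap = np.minimum(a.values, b.values).ravel()
        for bin_id in range(10):
            lo, hi = bin_id / 10, (bin_id + 1) / 10
            sel = (overlap >= lo) & ((overlap < hi) | (bin_id == 9))
            assert prof.table.loc[bin_id, "n_cells"] == sel.sum()
            if sel.sum() >= 2:
                va = a.values.ravel()[sel]
                tcrit = stats.t.ppf(0.975, df=sel.sum() - 1)
                half = tcrit * va.std(ddof=1) / np.sqrt(sel.sum())
                assert prof.table.loc[bin_id, "ci_A_low"] == pytest.approx(va.mean() - half)
            elif sel.sum() < 2:
                assert bool(prof.table.loc[bin_id, "flagged"])

    def test_bins_partition_unit_interval(self):
        rng = np.random.default_rng(8)
        a, b = random_surface(rng), random_surface(rng)
        prof = shared_favourability_profile(a, b, n_bins=10)
        np.testing.assert_allclose(prof.bin_edges, np.linspace(0, 1, 11))
        assert prof.table["n_cells"].sum() == a.values.size


class TestFuzzyEntropy:
    def test_crisp_zero_and_maximal(self):
        crisp = MembershipSurface(values=np.array([[0.0, 1.0, 1.0]]), kind="favourability")
        assert fuzzy_entropy(crisp) == 0.0
        half = MembershipSurface(values=np.full((2, 2), 0.5), kind="favourability")
        assert fuzzy_entropy(half) == pytest.approx(1.0)

    def test_hand_value(self):
        s = MembershipSurface(values=np.array([[0.25, 0.75]]), kind="favourability")
        assert fuzzy_entropy(s) == pytest.approx(1 / 3)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        s = random_surface(rng, shape=(3, 4))
        assert fuzzy_entropy(s) == pytest.approx(brute_entropy(s.values), abs=1e-12)
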