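"""Permutation folding: parity, optimal relabelling, nearest-site
classification, and consistency with wavefunction antisymmetry."""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dvms import (SpinFactoredSites, SpinPartition, VoronoiSite, best_fold,
                  nearest_site, permutation_parity)


def exhaustive_spin_fold(block, ref):
    """Oracle: try every relabelling of one spin block."""
    n = block.shape[0]
    best = None
    for perm in itertools.permutations(range(n)):
        d = float(np.sum((block[list(perm)] - ref) ** 2))
        if best is None or d < best[1] - 1e-12:
            best = (perm, d)
    return best


class TestParity:
    def test_identity_even(self):
        assert permutation_parity([0, 1, 2]) == 1

    def test_transposition_odd(self):
        assert permutation_parity([1, 0, 2]) == -1

    def test_matches_swap_count_oracle(self, rng):
        for _ in range(50):
            p = rng.permutation(8)
            swaps = 0
            q = list(p)
            for i in range(len(q)):
                while q[i] != i:
                    j = q[i]
                    q[i], q[j] = q[j], q[i]
                    swaps += 1
            assert permutation_parity(p) == (-1) ** swaps

    def test_multiplicative_under_composition(self, rng):
        p = rng.permutation(6)
        q = rng.permutation(6)
        assert (permutation_parity(p[q]) ==
                permutation_parity(p) * permutation_parity(q))

    def test_non_bijection_rejected(self):
        with pytest.raises(ValueError):
            permutation_parity([0, 0, 1])


class TestBestFold:
    def test_point_at_site_is_identity(self, triplet_toy):
        site = triplet_toy.sites[0]
        f = best_fold(site.point, site)
        assert f.parity == 1
        assert f.sq_distance == pytest.approx(0.0)
        assert list(f.alpha_perm) == [0, 1]

    def test_swapped_pair_is_transposition(self, triplet_toy):
        site = triplet_toy.sites[0]
        x = site.point[[1, 0]]
        f = best_fold(x, site)
        assert f.parity == -1
        np.testing.assert_allclose(f.folded, site.point)

    @pytest.mark.parametrize("na,nb", [(3, 2), (4, 4), (5, 3)])
    def test_matches_exhaustive_enumeration(self, rng, na, nb):
        part = SpinPartition(na, nb)
        n_trials = 1000 // (na + nb)
        for _ in range(n_trials):
            site = VoronoiSite(rng.normal(size=(na + nb, 3)), part)
            x = rng.normal(size=(na + nb, 3))
            f = best_fold(x, site)
            _, da = exhaustive_spin_fold(x[:na], site.alpha)
            _, db = exhaustive_spin_fold(x[na:], site.beta)
            assert f.sq_distance == pytest.approx(da + db, rel=1e-12)
            assert f.sq_distance <= np.sum((x - site.point) ** 2) + 1e-12

    def test_folding_idempotent(self, rng):
        part = SpinPartition(4, 4)
        site = VoronoiSite(rng.normal(size=(8, 3)), part)
        x = rng.normal(size=(8, 3))
        f1 = best_fold(x, site)
        f2 = best_fold(f1.folded, site)
        assert list(f2.alpha_perm) == list(range(4))
        assert list(f2.beta_perm) == list(range(4))
        assert f2.sq_distance == pytest.approx(f1.sq_distance, rel=1e-12)

    def test_distance_invariant_under_prior_relabelling(self, rng):
        part = SpinPartition(4, 3)
        site = VoronoiSite(rng.normal(size=(7, 3)), part)
        x = rng.normal(size=(7, 3))
        base = best_fold(x, site).sq_distance
        pa = rng.permutation(4)
        pb = rng.permutation(3)
        x2 = np.concatenate([x[:4][pa], x[4:][pb]])
        assert best_fold(x2, site).sq_distance == pytest.approx(base,
                                                                rel=1e-12)

    def test_fold_preserves_wavefunction_magnitude(self, rng, triplet_toy):
        ci = triplet_toy.ci
        site = triplet_toy.sites[0]
        for _ in range(20):
            x = rng.normal(size=(2, 3))
            f = best_fold(x, site)
            v, vf = ci.value(x), ci.value(f.folded)
            assert abs(vf) == pytest.approx(abs(v), rel=1e-12)
            assert vf == pytest.approx(f.parity * v, rel=1e-12)


class TestNearestSite:
    def test_exact_site_wins_with_zero_distance(self, double_well_toy):
        sites = double_well_toy.sites
        i, f = nearest_site(sites[1].point, sites)
        assert i == 1
        assert f.sq_distance == pytest.approx(0.0)

    def test_empty_site_list_rejected(self):
        with pytest.raises(ValueError):
            nearest_site(np.zeros((1, 3)), [])

    def test_matches_exhaustive_enumeration_two_sites(self, rng):
        part = SpinPartition(3, 0)
        s1 = VoronoiSite(rng.normal(size=(3, 3)), part, "s1")
        s2 = VoronoiSite(rng.normal(size=(3, 3)), part, "s2")
        for _ in range(200):
            x = rng.normal(scale=1.5, size=(3, 3))
            i, f = nearest_site(x, [s1, s2])
            d1 = exhaustive_spin_fold(x, s1.alpha)[1]
            d2 = exhaustive_spin_fold(x, s2.alpha)[1]
            assert i == (0 if d1 <= d2 else 1)
            assert f.sq_distance == pytest.approx(min(d1, d2), rel=1e-12)


class TestSpinFactoredSites:
    def test_matches_general_nearest_site(self, rng):
        part = SpinPartition(3, 3)
        a0, a1 = rng.normal(size=(2, 3, 3))
        b0, b1 = rng.normal(size=(2, 3, 3))
        fac = SpinFactoredSites([a0, a1], [b0, b1], part)
        sites = fac.sites
        X = rng.normal(scale=1.2, size=(100, 6, 3))
        idx, _ = fac.classify(X)
        for w in range(X.shape[0]):
            i_ref, _ = nearest_site(X[w], sites)
            assert idx[w] == i_ref

    def test_parity_constrained_distance_matches_enumeration(self, rng):
        part = SpinPartition(3, 2)
        fac = SpinFactoredSites([rng.normal(size=(3, 3))],
                                [rng.normal(size=(2, 3))], part)
        X = rng.normal(scale=1.2, size=(50, 5, 3))
        for req in (1, -1):
            _, d2 = fac.classify(X, parities=[req])
            for w in range(X.shape[0]):
                best = np.inf
                for pa in itertools.permutations(range(3)):
                    for pb in itertools.permutations(range(2)):
                        par = (permutation_parity(list(pa))
                               * permutation_parity(list(pb)))
                        if par != req:
                            continue
                        c = (np.sum((X[w, :3][list(pa)]
                                     - fac.alpha_variants[0]) ** 2)
                             + np.sum((X[w, 3:][list(pb)]
                                       - fac.beta_variants[0]) ** 2))
                        best = min(best, c)
                assert d2[w, 0] == pytest.approx(best, rel=1e-10)


class TestEvenFold:
    def test_swapped_pair_repaired_to_even(self, rng):
        from dvms.fold import even_fold
        part = SpinPartition(2, 0)
        site = VoronoiSite(np.array([[-1.0, 0, 0], [1.0, 0, 0]]), part)
        x = np.array([[0.9, 0.1, 0], [-0.8, 0, 0.1]])  # swapped order
        f, was_odd = even_fold(x, site)
        assert was_odd
        assert f.parity == 1
        # the even fold is the identity here (only two relabellings exist)
        np.testing.assert_allclose(f.folded, x)

    def test_even_fold_matches_constrained_enumeration(self, rng):
        from dvms.fold import best_fold
        part = SpinPartition(4, 0)
        for _ in range(100):
            site = VoronoiSite(rng.normal(size=(4, 3)), part)
            x = rng.normal(size=(4, 3))
            f = best_fold(x, site, parity=1)
            assert f.parity == 1
            best = min(
                (np.sum((x[list(p)] - site.point) ** 2))
                for p in itertools.permutations(range(4))
                if permutation_parity(list(p)) == 1)
            assert f.sq_distance == pytest.approx(best, rel=1e-10)
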