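"""Occupancy statistics: reference-site construction, equilibrium
estimates with decorrelation-corrected errors, kinetic fits, and block
stationarity, checked against synthetic two-state Markov traces with known
moments."""
import numpy as np
import pytest

from dvms import (OccupancyTrace, VoronoiSite, best_fold, block_stationarity,
                  build_reference_sites, build_benzene, equilibrium_occupancy,
                  fit_kinetics, lewis_guess)
from dvms.occupancy import IS_STAGGERED, SITE_LABELS, \
    identify_cc_bonding_electrons
from dvms.wavefunction import SpinPartition


def markov_trace(n_walkers, n_steps, p_es, p_se, rng, start_staggered=0):
    """Independent two-state walkers: eclipsed -> staggered with prob p_es
    per step, reverse p_se. Returns an OccupancyTrace with two active
    sites."""
    state = np.zeros(n_walkers, dtype=bool)
    state[:start_staggered] = True
    counts = np.zeros((n_steps, 4), dtype=int)
    for k in range(n_steps):
        u = rng.random(n_walkers)
        flip = np.where(state, u < p_se, u < p_es)
        state = state ^ flip
        counts[k, 0] = np.sum(~state)
        counts[k, 1] = np.sum(state)
    return OccupancyTrace(site_counts=counts, n_walkers=n_walkers,
                          metadata={"synthetic": True})


class TestReferenceSites:
    @pytest.fixture(scope="class")
    def base(self):
        geo = build_benzene()
        part = SpinPartition(21, 21)
        return geo, VoronoiSite(lewis_guess(geo), part, "base")

    def test_cc_bonding_set_has_nine_per_spin(self, base):
        geo, site = base
        assert len(identify_cc_bonding_electrons(site.alpha, geo)) == 9
        assert len(identify_cc_bonding_electrons(site.beta, geo)) == 9

    def test_four_sites_with_expected_labels(self, base):
        geo, site = base
        fac = build_reference_sites(site, geo)
        assert tuple(s.label for s in fac.sites) == SITE_LABELS
        assert sum(IS_STAGGERED) == 2

    def test_alpha_rotation_changes_only_cc_electrons(self, base):
        geo, site = base
        fac = build_reference_sites(site, geo)
        stag_b = fac.sites[2]  # alpha rotated
        moved = np.any(np.abs(stag_b.alpha - site.alpha) > 1e-12, axis=1)
        assert moved.sum() == 9
        np.testing.assert_allclose(stag_b.beta, site.beta)

    def test_double_rotation_closes_onto_base_modulo_permutation(self, base):
        # rotating both C-C spin sets twice by 60 deg = 120 deg rotation,
        # which maps the Kekulé pattern onto itself
        geo, site = base
        fac1 = build_reference_sites(site, geo)
        fac2 = build_reference_sites(fac1.sites[3], geo)
        f = best_fold(fac2.sites[3].point, site)
        assert f.sq_distance < 1e-16

    def test_staggered_pair_related_by_spin_swap(self, base):
        geo, site = base
        fac = build_reference_sites(site, geo)
        sA, sB = fac.sites[1], fac.sites[2]
        swapped = np.concatenate([sA.beta, sA.alpha])
        f = best_fold(swapped, sB)
        assert f.sq_distance < 1e-16


class TestOccupancyTrace:
    def test_count_conservation_enforced(self):
        bad = np.array([[3, 1, 0, 0], [2, 1, 0, 0]])
        with pytest.raises(ValueError):
            OccupancyTrace(site_counts=bad, n_walkers=4, metadata={})

    def test_class_sums(self):
        counts = np.array([[2, 1, 1, 0]])
        tr = OccupancyTrace(site_counts=counts, n_walkers=4, metadata={})
        assert tr.eclipsed[0] == 2 and tr.staggered[0] == 2


class TestEquilibriumOccupancy:
    def test_constant_trace_zero_se(self):
        counts = np.tile([3, 2, 2, 3], (500, 1))
        tr = OccupancyTrace(site_counts=counts, n_walkers=10, metadata={})
        est = equilibrium_occupancy(tr, 0, 500)
        assert est.mean_eclipsed == 6.0
        assert est.se_eclipsed == 0.0

    def test_short_window_rejected(self):
        counts = np.tile([1, 1, 0, 0], (300, 1))
        tr = OccupancyTrace(site_counts=counts, n_walkers=2, metadata={})
        with pytest.raises(ValueError):
            equilibrium_occupancy(tr, 200, 300)

    def test_markov_mean_and_se_within_three_sigma(self):
        rng = np.random.default_rng(99)
        p = 0.01  # symmetric switching; equilibrium 50/50
        tr = markov_trace(200, 3000, p, p, rng)
        est = equilibrium_occupancy(tr, 1000, 3000, decorrelation_steps=100)
        # analytic: mean 100, per-step SD sqrt(W/4); relaxation 1/(2p)=50
        assert abs(est.mean_staggered - 100.0) < 3 * est.se_staggered
        # the decorrelation-corrected SE should be of the right order:
        # true SE = SD * sqrt(2*tau_int / n); tau ~ 50 steps
        sd = np.sqrt(200 / 4)
        true_se = sd * np.sqrt(2 * 50 / 2000)
        assert est.se_staggered == pytest.approx(true_se, rel=0.6)

    def test_interval_calibration_on_replicates(self):
        # 2-sigma interval should cover the true mean in >= 90% of seeds
        p = 0.02
        cover = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            tr = markov_trace(100, 1200, p, p, rng, start_staggered=50)
            est = equilibrium_occupancy(tr, 200, 1200,
                                        decorrelation_steps=1 / p)
            if abs(est.mean_staggered - 50.0) <= 2 * est.se_staggered:
                cover += 1
        assert cover >= 90


class TestFitKinetics:
    def test_known_relaxation_rate_recovered(self):
        # clean exponential relaxation plus iid noise
        rng = np.random.default_rng(5)
        k = np.arange(1, 2001)
        y = 250.0 - 250.0 * np.exp(-0.01 * k)
        counts = np.round(y + rng.normal(scale=5.0, size=y.size)).astype(int)
        counts = np.clip(counts, 0, 500)
        tr = OccupancyTrace(
            site_counts=np.stack([500 - counts, counts,
                                  np.zeros_like(counts),
                                  np.zeros_like(counts)], axis=1),
            n_walkers=500, metadata={})
        fit = fit_kinetics(tr)
        assert fit.identifiable
        assert fit.relaxation_rate == pytest.approx(0.01, rel=0.10)
        assert fit.crossing_rate == pytest.approx(0.005, rel=0.10)
        assert fit.decorrelation_steps == pytest.approx(200, rel=0.10)

    def test_markov_realization_rate_order(self):
        rng = np.random.default_rng(55)
        # p_es = p_se = 0.005 -> relaxation rate 0.01 per step; a single
        # realization carries correlated noise, so allow a loose band
        tr = markov_trace(500, 2000, 0.005, 0.005, rng)
        fit = fit_kinetics(tr)
        assert fit.identifiable
        assert fit.relaxation_rate == pytest.approx(0.01, rel=0.35)

    def test_equilibrium_start_flagged_unidentifiable(self):
        rng = np.random.default_rng(6)
        tr = markov_trace(400, 1500, 0.01, 0.01, rng, start_staggered=200)
        fit = fit_kinetics(tr)
        assert not fit.identifiable


class TestBlockStationarity:
    def test_identical_blocks_pass(self):
        counts = np.tile([5, 5, 0, 0], (2000, 1))
        tr = OccupancyTrace(site_counts=counts, n_walkers=10, metadata={})
        reports = block_stationarity(tr, [(500, 1000), (1000, 1500),
                                          (1500, 2000)])
        assert len(reports) == 3
        assert all(r.passed for r in reports)

    def test_large_mean_shift_fails(self):
        rng = np.random.default_rng(11)
        a = markov_trace(100, 1000, 0.02, 0.02, rng, start_staggered=50)
        b = markov_trace(100, 1000, 0.08, 0.02, rng, start_staggered=50)
        counts = np.concatenate([a.site_counts, b.site_counts])
        tr = OccupancyTrace(site_counts=counts, n_walkers=100, metadata={})
        reports = block_stationarity(tr, [(400, 1000), (1400, 2000)],
                                     decorrelation_steps=25)
        assert not reports[0].passed

    def test_equilibrated_markov_blocks_pass(self):
        rng = np.random.default_rng(12)
        tr = markov_trace(200, 2000, 0.01, 0.01, rng, start_staggered=100)
        reports = block_stationarity(tr, [(500, 1000), (1000, 1500),
                                          (1500, 2000)],
                                     decorrelation_steps=50)
        assert sum(r.passed for r in reports) >= 2

    def test_overlapping_blocks_rejected(self):
        counts = np.tile([1, 1, 0, 0], (1000, 1))
        tr = OccupancyTrace(site_counts=counts, n_walkers=2, metadata={})
        with pytest.raises(ValueError):
            block_stationarity(tr, [(0, 500), (400, 900)])
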