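import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from codonscape import code_model as cm
from codonscape import niching

from .oracles import oracle_distance

PEAKS = (0.0797, 0.2465, 0.4507, 0.6812, 0.9340)


class TestCodeDistance:
    def test_self_distance_is_zero(self, rng):
        g = cm.random_restrictive(rng)
        assert niching.code_distance(g, g) == 0.0
        u = cm.random_unrestrictive(rng)
        assert niching.code_distance(u, u) == 0.0

    def test_symmetry_and_range_on_random_pairs(self, rng):
        for _ in range(300):
            a, b = cm.random_restrictive(rng), cm.random_restrictive(rng)
            d1, d2 = niching.code_distance(a, b), niching.code_distance(b, a)
            assert d1 == d2
            assert 0.0 <= d1 <= 1.0
        for _ in range(100):
            a, b = cm.random_unrestrictive(rng), cm.random_unrestrictive(rng)
            d = niching.code_distance(a, b)
            assert d == niching.code_distance(b, a)
            assert 0.0 <= d <= 1.0

    def test_asp_cys_swap_matches_closed_form(self):
        # swapping the two polarity extremes at two positions gives
        # sqrt(2 * 8.2^2) / (8.2 * sqrt(20)) = sqrt(2/20)
        p = np.arange(20)
        q = p.copy()
        di, ci = cm.AMINO_INDEX["D"], cm.AMINO_INDEX["C"]
        q[di], q[ci] = q[ci], q[di]
        d = niching.code_distance(
            cm.RestrictiveGenotype(perm=p), cm.RestrictiveGenotype(perm=q)
        )
        assert d == pytest.approx(np.sqrt(2 / 20), rel=1e-12)

    def test_unrestrictive_skips_stop_positions_but_keeps_L_64(self, rng):
        for _ in range(20):
            a, b = cm.random_unrestrictive(rng), cm.random_unrestrictive(rng)
            ta = cm.from_compact(cm.to_compact(a))
            tb = cm.from_compact(cm.to_compact(b))
            assert niching.code_distance(a, b) == pytest.approx(
                oracle_distance(ta, tb, length=64), rel=1e-10
            )

    def test_model_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            niching.code_distance(
                cm.random_restrictive(rng), cm.random_unrestrictive(rng)
            )

    def test_restrictive_interdistances_rarely_exceed_0_6(self):
        # many amino acids share similar polarity, so large inter-distances
        # are hard to realize even between unrelated permutations
        rng = np.random.default_rng(17)
        perms = rng.permuted(np.tile(np.arange(20), (200, 1)), axis=1)
        dm = niching.distance_matrix(perms, "restrictive")
        pairs = dm[np.triu_indices(200, k=1)]
        assert np.quantile(pairs, 0.99) < 0.65

    @pytest.mark.parametrize("model", ["restrictive", "unrestrictive"])
    def test_distance_matrix_matches_pairwise_calls(self, rng, model):
        if model == "restrictive":
            pop = np.stack([cm.random_restrictive(rng).perm for _ in range(8)])
            wrap = cm.RestrictiveGenotype
        else:
            pop = np.stack([cm.random_unrestrictive(rng).assign for _ in range(8)])
            wrap = cm.UnrestrictiveGenotype
        dm = niching.distance_matrix(pop, model)
        assert np.allclose(dm, dm.T) and np.allclose(np.diag(dm), 0.0)
        for i in range(8):
            for j in range(i + 1, 8):
                assert dm[i, j] == pytest.approx(
                    niching.code_distance(wrap(pop[i]), wrap(pop[j])), abs=1e-10
                )


class TestSharingFunction:
    def test_boundary_identities(self):
        cfg = niching.SharingConfig(sigma_share=0.1, alpha=1.0)
        assert niching.sharing_value(0.0, cfg) == 1.0
        assert niching.sharing_value(0.1, cfg) == 0.0
        assert niching.sharing_value(0.2, cfg) == 0.0
        assert niching.sharing_value(0.05, cfg) == pytest.approx(0.5)

    @settings(deadline=None, derandomize=True)
    @given(
        d=st.floats(0, 1),
        sigma=st.floats(0.01, 1.0),
        alpha=st.floats(0.5, 3.0),
    )
    def test_kernel_stays_in_unit_interval(self, d, sigma, alpha):
        cfg = niching.SharingConfig(sigma_share=sigma, alpha=alpha)
        v = niching.sharing_value(d, cfg)
        assert 0.0 <= v <= 1.0

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            niching.SharingConfig(sigma_share=0.0)
        with pytest.raises(ValueError):
            niching.SharingConfig(sigma_share=0.1, alpha=0.0)


class TestSharedCosts:
    def test_isolated_population_keeps_raw_costs(self):
        cfg = niching.SharingConfig(sigma_share=0.1)
        costs = np.array([1.0, 2.0, 3.0])
        dm = np.array([[0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]])
        np.testing.assert_allclose(niching.shared_costs(costs, dm, cfg), costs)

    def test_duplicated_individual_pays_double(self):
        cfg = niching.SharingConfig(sigma_share=0.1)
        costs = np.array([1.0, 1.0, 5.0])
        dm = np.array([[0, 0.0, 0.9], [0.0, 0, 0.9], [0.9, 0.9, 0]])
        shared = niching.shared_costs(costs, dm, cfg)
        assert shared[0] == pytest.approx(2.0) and shared[1] == pytest.approx(2.0)
        assert shared[2] == pytest.approx(5.0)

    def test_shared_cost_never_below_raw(self, rng):
        cfg = niching.SharingConfig(sigma_share=0.3)
        for _ in range(20):
            perms = np.stack([cm.random_restrictive(rng).perm for _ in range(10)])
            costs = rng.uniform(1, 10, 10)
            dm = niching.distance_matrix(perms, "restrictive")
            assert np.all(niching.shared_costs(costs, dm, cfg) >= costs - 1e-12)

    def test_vanishing_radius_recovers_raw_costs(self, rng):
        perms = np.stack([cm.random_restrictive(rng).perm for _ in range(10)])
        costs = rng.uniform(1, 10, 10)
        dm = niching.distance_matrix(perms, "restrictive")
        tiny = niching.shared_costs(costs, dm, niching.SharingConfig(1e-9))
        np.testing.assert_allclose(tiny, costs)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            niching.shared_costs(
                np.ones(3), np.zeros((2, 2)), niching.SharingConfig(0.1)
            )


class TestDemoFunctions:
    def test_five_peaks_located_by_grid_search(self):
        xs = np.linspace(0, 1, 200_001)
        f = niching.five_peak_function(xs)
        interior = (f[1:-1] > f[:-2]) & (f[1:-1] > f[2:])
        maxima = xs[1:-1][interior]
        assert len(maxima) == 5
        for found, expected in zip(sorted(maxima), PEAKS):
            assert abs(found - expected) < 0.005

    def test_peak_heights_strictly_decrease_and_first_is_global(self):
        heights = [niching.five_peak_function(p) for p in PEAKS]
        assert all(a > b for a, b in zip(heights, heights[1:]))
        xs = np.linspace(0, 1, 10_001)
        assert abs(xs[np.argmax(niching.five_peak_function(xs))] - PEAKS[0]) < 0.005

    def test_domain_violation_raises(self):
        with pytest.raises(ValueError):
            niching.five_peak_function(1.5)

    def test_parabola_values_and_symmetry(self):
        assert niching.parabola_function(0.0) == 1.0
        assert niching.parabola_function(1.0) == 2.0
        assert niching.parabola_function(-1.0) == 2.0
        xs = np.linspace(-1, 1, 101)
        np.testing.assert_allclose(
            niching.parabola_function(xs), niching.parabola_function(-xs)
        )


class TestNichingDemo:
    def test_sharing_populates_at_least_four_peaks(self):
        xs, _ = niching.real_parameter_ga(
            niching.five_peak_function,
            domain=(0.0, 1.0),
            minimize=False,
            sharing=niching.SharingConfig(sigma_share=0.1),
            seed=0,
        )
        occupied = sum(np.any(np.abs(xs - p) < 0.02) for p in PEAKS)
        assert occupied >= 4

    def test_without_sharing_population_collapses_to_global_peak(self):
        xs, _ = niching.real_parameter_ga(
            niching.five_peak_function, domain=(0.0, 1.0), minimize=False, seed=0
        )
        assert np.mean(np.abs(xs - PEAKS[0]) < 0.02) >= 0.9

    def test_sharing_spreads_the_parabola_population(self):
        tight, _ = niching.real_parameter_ga(
            niching.parabola_function, domain=(-1.0, 1.0), minimize=True, seed=0
        )
        spread, _ = niching.real_parameter_ga(
            niching.parabola_function,
            domain=(-1.0, 1.0),
            minimize=True,
            sharing=niching.SharingConfig(sigma_share=0.1),
            seed=0,
        )
        assert spread.std() > 3 * tight.std()
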