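import numpy as np
import pytest

import icmgraph as ig
from icmgraph.core_io import Lineage
from icmgraph.correlation import Channel, Strength
from icmgraph.populations import PopulationLabel
from tests.conftest import make_embryo


class TestNeighbourMedian:
    def _embryo(self, gata6):
        # star: c0 at origin connected to all others
        n = len(gata6)
        pos = [[0, 0, 0]] + [
            [10 * np.cos(2 * np.pi * k / (n - 1)),
             10 * np.sin(2 * np.pi * k / (n - 1)), 5.0 * (k % 2)]
            for k in range(n - 1)
        ]
        return make_embryo(pos, [Lineage.ICM] * n, gata6=gata6)

    def test_odd_count_median(self):
        e = self._embryo([99.0, 1.0, 2.0, 3.0])
        g = ig.build_embryo_graph(e)
        assert ig.neighbour_median("c0", e, g, Channel.GATA6) == 2.0

    def test_even_count_midpoint(self):
        e = self._embryo([99.0, 1.0, 2.0, 3.0, 4.0])
        g = ig.build_embryo_graph(e)
        assert ig.neighbour_median("c0", e, g, Channel.GATA6) == 2.5

    def test_no_in_scope_neighbours_undefined(self):
        pos = [[0, 0, 0], [10, 0, 0], [11, 5, 0]]
        e = make_embryo(pos, [Lineage.ICM, Lineage.TE, Lineage.TE])
        g = ig.build_embryo_graph(e)
        assert ig.neighbour_median("c0", e, g, Channel.GATA6,
                                   scope="icm_only") is None


class TestSpearman:
    def test_co_monotone(self):
        pairs = np.column_stack([np.arange(5.0), np.arange(5.0) ** 2])
        rho, n = ig.spearman_neighbourhood(pairs)
        assert rho == pytest.approx(1.0) and n == 5

    def test_anti_monotone(self):
        pairs = np.column_stack([np.arange(5.0), -np.arange(5.0)])
        assert ig.spearman_neighbourhood(pairs)[0] == pytest.approx(-1.0)

    def test_hand_computed_rho(self):
        # d^2 sum = 2 -> rho = 1 - 6*2 / (5 * 24) = 0.9
        pairs = np.column_stack([[1, 2, 3, 4, 5], [2, 1, 3, 4, 5]])
        assert ig.spearman_neighbourhood(pairs)[0] == pytest.approx(0.9)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        y = x + rng.normal(scale=0.5, size=40)
        base = ig.spearman_neighbourhood(np.column_stack([x, y]))[0]
        transformed = ig.spearman_neighbourhood(
            np.column_stack([np.exp(x), y**3]))[0]
        assert transformed == pytest.approx(base)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            ig.spearman_neighbourhood(np.array([[1.0, 2.0], [2.0, 3.0]]))


class TestBootstrap:
    def test_perfect_monotone_zero_se(self):
        pairs = np.column_stack([np.arange(10.0), np.arange(10.0)])
        assert ig.bootstrap_se(pairs, reps=50, seed=1) == 0.0

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(0)
        pairs = rng.normal(size=(30, 2))
        assert ig.bootstrap_se(pairs, seed=5) == ig.bootstrap_se(pairs, seed=5)

    def test_se_shrinks_with_sample_size(self):
        rng = np.random.default_rng(9)
        ses = {}
        for n in (50, 200, 800):
            x = rng.normal(size=n)
            y = 0.6 * x + 0.8 * rng.normal(size=n)
            ses[n] = ig.bootstrap_se(np.column_stack([x, y]), reps=100, seed=2)
        assert ses[50] > ses[200] > ses[800]
        ratio = ses[50] / ses[800]
        assert 2.0 < ratio < 8.0  # roughly 1/sqrt(n): expected 4


class TestShuffleNull:
    def test_level_multiset_preserved_and_geometry_fixed(self, normalized_cohort):
        e = normalized_cohort.embryos[0]
        rng = np.random.default_rng(0)
        shuffled = ig.correlation.shuffle_embryo_levels(e, rng)
        pairs = sorted((n.level_nanog, n.level_gata6) for n in e.icm_nuclei())
        pairs_s = sorted((n.level_nanog, n.level_gata6)
                         for n in shuffled.icm_nuclei())
        assert pairs == pairs_s
        assert np.allclose(e.positions(), shuffled.positions())
        assert ig.build_embryo_graph(e).edges == \
            ig.build_embryo_graph(shuffled).edges
        te_levels = [(n.level_nanog, n.level_gata6) for n in e.te_nuclei()]
        te_s = [(n.level_nanog, n.level_gata6) for n in shuffled.te_nuclei()]
        assert te_levels == te_s

    def test_null_mean_near_zero_without_planted_clustering(self):
        # correlation length far below cell spacing: GATA6 is spatially
        # unstructured, so the pooled null and observed rho agree near 0
        cohort = ig.generate_cohort({"early": 8}, seed=21, gata6_corr_length=0.5)
        norm = ig.align_batches(cohort, [ig.reference_thresholds()])
        graphs = {e.embryo_id: ig.build_embryo_graph(e) for e in norm}
        null = ig.shuffle_null(norm, graphs, PopulationLabel.DP,
                               Channel.GATA6, Channel.GATA6, reps=60, seed=3)
        # permuting within small finite pools leaves a slight negative
        # exchangeability bias, so "near zero" is judged against the
        # null's own spread
        assert abs(null.mean()) < 3 * null.std(ddof=1)
        assert abs(null.mean()) < 0.15


class TestNullComparison:
    def test_identical_samples_capped_at_one(self):
        x = np.array([0.1, 0.2, 0.3])
        assert ig.null_comparison(x, x) == 1.0

    def test_exact_small_sample_p(self):
        # complete separation of 2 vs 2: exact two-sided p = 2/C(4,2) = 1/3
        p = ig.null_comparison(np.array([0.8, 0.9]), np.array([0.1, 0.2]))
        assert p == pytest.approx(1 / 3)

    def test_disjoint_large_samples_tiny_p(self):
        rng = np.random.default_rng(1)
        obs = rng.normal(0.8, 0.01, 100)
        null = rng.normal(0.0, 0.01, 100)
        assert ig.null_comparison(obs, null) < 1e-6


class TestStrengthAndReliability:
    @pytest.mark.parametrize(
        "rho,band",
        [(0.0, Strength.VERY_WEAK), (0.19, Strength.VERY_WEAK),
         (0.20, Strength.WEAK), (0.39, Strength.WEAK),
         (0.45, Strength.MODERATE), (0.60, Strength.STRONG),
         (-0.65, Strength.STRONG), (0.80, Strength.VERY_STRONG),
         (1.0, Strength.VERY_STRONG)],
    )
    def test_evans_bands(self, rho, band):
        assert ig.classify_strength(rho) is band

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ig.classify_strength(1.01)

    @pytest.mark.parametrize("n,ok", [(0, False), (107, False), (108, True),
                                      (500, True)])
    def test_reliability_gate(self, n, ok):
        assert ig.reliability_gate(n) is ok


class TestSensitivity:
    def test_trivial_threshold_returns_smallest(self):
        rng = np.random.default_rng(4)
        pairs = rng.normal(size=(100, 2))
        assert ig.sensitivity_min_n(pairs, [10, 20, 50], reps=20,
                                    variability_threshold=2.0, seed=1) == 10

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(4)
        pairs = rng.normal(size=(200, 2))
        a = ig.sensitivity_min_n(pairs, [20, 50, 100], reps=30, seed=7)
        b = ig.sensitivity_min_n(pairs, [20, 50, 100], reps=30, seed=7)
        assert a == b

    def test_stronger_correlation_needs_fewer_cells(self):
        rng = np.random.default_rng(6)
        n = 600
        x = rng.normal(size=n)
        grid = [25, 50, 100, 200, 400]
        required = {}
        for label, slope in (("strong", 3.0), ("weak", 0.3)):
            y = slope * x + rng.normal(size=n)
            req = ig.sensitivity_min_n(np.column_stack([x, y]), grid,
                                       reps=60, seed=2)
            required[label] = req if req is not None else np.inf
        assert required["strong"] <= required["weak"]


class TestPlantedClusteringRecovery:
    def test_dp_gata6_correlation_recovered(self, normalized_cohort, graphs,
                                            labels):
        """GATA6 spatial clustering planted at 15 um correlation length is
        recovered as at least a moderate DP-cell neighbourhood correlation,
        significantly above the shuffle null."""
        res = ig.correlate_population(
            normalized_cohort, graphs, labels, PopulationLabel.DP,
            Channel.GATA6, Channel.GATA6, bootstrap_reps=50, null_reps=50,
            seed=11,
        )
        assert res is not None
        assert res.rho > 0.4
        assert res.reliable
        assert res.null_p_adjusted is not None and res.null_p_adjusted < 0.05
        pairs = ig.collect_pairs(normalized_cohort, graphs, labels,
                                 PopulationLabel.DP, Channel.GATA6,
                                 Channel.GATA6)
        null = ig.shuffle_null(normalized_cohort, graphs, PopulationLabel.DP,
                               Channel.GATA6, Channel.GATA6, reps=50, seed=13)
        assert res.rho > np.percentile(null, 97.5)

    def test_nanog_shows_no_expression_clustering(self, normalized_cohort,
                                                  graphs, labels):
        """NANOG has no planted spatial field, so its neighbourhood
        correlation stays below the weak band."""
        pairs = ig.collect_pairs(normalized_cohort, graphs, labels, None,
                                 Channel.NANOG, Channel.NANOG)
        rho, _ = ig.spearman_neighbourhood(pairs)
        assert abs(rho) < 0.2
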