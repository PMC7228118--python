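import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import icmgraph as ig
from icmgraph.core_io import Lineage, Stage
from tests.conftest import make_embryo


class TestStaging:
    @pytest.mark.parametrize(
        "count,expected",
        [(32, Stage.EARLY), (64, Stage.EARLY), (65, Stage.MID),
         (90, Stage.MID), (91, Stage.LATE), (200, Stage.LATE)],
    )
    def test_boundaries(self, count, expected):
        assert ig.stage_embryo(count) is expected

    def test_below_range_rejected(self):
        with pytest.raises(ValueError):
            ig.stage_embryo(31)

    @given(st.integers(32, 500))
    def test_total_function_partitions(self, count):
        stage = ig.stage_embryo(count)
        assert stage in (Stage.EARLY, Stage.MID, Stage.LATE)
        # interval membership is mutually exclusive and exhaustive
        assert (stage is Stage.EARLY) == (32 <= count <= 64)
        assert (stage is Stage.MID) == (65 <= count <= 90)
        assert (stage is Stage.LATE) == (count > 90)


class TestOutlierFilter:
    def test_zero_spread_all_kept(self):
        assert ig.filter_intensity_outliers(np.array([1.0, 1, 1, 1])).all()

    def test_hand_computed_outlier(self):
        # mean 17.5, sample SD 40.4; only 100 is beyond 2 SD... check by hand:
        vals = np.array([1.0, 1, 1, 1, 1, 100])
        mean, sd = vals.mean(), vals.std(ddof=1)
        expected = np.abs(vals - mean) <= 2 * sd
        mask = ig.filter_intensity_outliers(vals, k=2)
        assert (mask == expected).all()
        assert not mask[-1] and mask[:-1].all()

    @given(st.integers(0, 50))
    @settings(max_examples=20, deadline=None)
    def test_monotone_in_k(self, seed):
        vals = np.random.default_rng(seed).normal(size=30)
        k2 = ig.filter_intensity_outliers(vals, k=2)
        k3 = ig.filter_intensity_outliers(vals, k=3)
        assert (k3 | ~k2).all()  # kept at k=2 implies kept at k=3

    def test_chebyshev_keep_fraction(self):
        vals = np.random.default_rng(0).normal(size=5000)
        mask = ig.filter_intensity_outliers(vals, k=2)
        assert mask.mean() >= 1 - 1 / 4


class TestKMeansThreshold:
    def test_two_point_masses(self):
        levels = np.array([1.0] * 50 + [100.0] * 50)
        assert ig.derive_threshold_kmeans(levels) == pytest.approx(10.0)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        levels = np.exp(rng.normal(0, 1, 200)) + np.repeat([0.0, 50.0], 100)
        t1 = ig.derive_threshold_kmeans(levels)
        t2 = ig.derive_threshold_kmeans(7.5 * levels)
        assert t2 == pytest.approx(7.5 * t1, rel=1e-9)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            ig.derive_threshold_kmeans(np.full(10, 5.0))


class TestAlignBatches:
    def _cohort(self, batches):
        embryos = []
        for k, (batch, nanog, gata6) in enumerate(batches):
            e = make_embryo([[0, 0, 0]], [Lineage.ICM], nanog=[nanog],
                            gata6=[gata6], embryo_id=f"e{k}")
            e.batch_id = batch
            embryos.append(e)
        return ig.Cohort(label="t", embryos=embryos)

    def test_boundary_maps_to_one(self):
        cohort = self._cohort([("b1", 100.0, 50.0)])
        thr = [ig.Thresholds(batch_id="b1", thr_nanog=100, thr_gata6=50)]
        norm = ig.align_batches(cohort, thr)
        n = norm.embryos[0].nuclei[0]
        assert n.level_nanog == pytest.approx(1.0)
        assert n.level_gata6 == pytest.approx(1.0)
        assert norm.units_note == "normalized"

    def test_cross_batch_scale_invariance(self):
        cohort = self._cohort([("b1", 150.0, 150.0), ("b2", 300.0, 300.0)])
        thr = [ig.Thresholds(batch_id="b1", thr_nanog=100, thr_gata6=100),
               ig.Thresholds(batch_id="b2", thr_nanog=200, thr_gata6=200)]
        norm = ig.align_batches(cohort, thr)
        levels = [e.nuclei[0].level_nanog for e in norm]
        assert levels == pytest.approx([1.5, 1.5])

    def test_missing_batch_named(self):
        cohort = self._cohort([("b9", 1.0, 1.0)])
        with pytest.raises(ValueError, match="b9"):
            ig.align_batches(cohort, [ig.Thresholds(batch_id="b1", thr_nanog=1,
                                                    thr_gata6=1)])

    def test_zero_threshold_rejected(self):
        with pytest.raises(ValueError):
            ig.Thresholds(batch_id="b", thr_nanog=0.0, thr_gata6=1.0)

    def test_idempotent_with_unit_thresholds(self):
        cohort = self._cohort([("b1", 2.0, 3.0)])
        thr = [ig.Thresholds(batch_id="b1", thr_nanog=1.0, thr_gata6=1.0)]
        once = ig.align_batches(cohort, thr)
        twice = ig.align_batches(once, thr)
        assert twice.embryos[0].nuclei[0].level_nanog == pytest.approx(
            once.embryos[0].nuclei[0].level_nanog)


class TestZDecay:
    def _embryo_with_decay(self, lam=50.0, n=60, seed=0):
        rng = np.random.default_rng(seed)
        pos = rng.uniform(0, 60, (n, 3))
        base = 100.0
        levels = base * np.exp(-pos[:, 2] / lam)
        return make_embryo(pos, [Lineage.ICM] * n, nanog=levels, gata6=levels)

    def test_model_none_is_identity(self):
        e = self._embryo_with_decay()
        out = ig.correct_z_decay(e, model="none")
        assert np.allclose(
            [n.level_nanog for n in out.nuclei],
            [n.level_nanog for n in e.nuclei],
        )

    def test_exponential_decay_flattened(self):
        e = self._embryo_with_decay(lam=50.0)
        out = ig.correct_z_decay(e, model="exponential")
        z = np.array([n.position[2] for n in out.nuclei])
        lv = np.array([n.level_nanog for n in out.nuclei])
        grand = lv.mean()
        for lo in range(0, 60, 15):
            sel = (z >= lo) & (z < lo + 15)
            if sel.sum() > 2:
                assert abs(lv[sel].mean() - grand) / grand < 0.05

    def test_increasing_trend_left_unchanged(self, caplog):
        e = self._embryo_with_decay()
        for n in e.nuclei:  # invert: level grows with depth
            n.level_nanog = 1.0 + n.position[2]
            n.level_gata6 = 1.0 + n.position[2]
        import logging
        with caplog.at_level(logging.WARNING):
            out = ig.correct_z_decay(e, model="exponential")
        assert "non-decaying" in caplog.text
        assert np.allclose(
            [n.level_nanog for n in out.nuclei],
            [n.level_nanog for n in e.nuclei],
        )


class TestRescalePositions:
    def test_identity(self):
        e = make_embryo([[0, 0, 1], [0, 0, 5]], [Lineage.ICM, Lineage.ICM])
        out = ig.rescale_positions(e, 1.0)
        assert np.allclose(out.positions(), e.positions())

    def test_z_separation_doubles(self):
        e = make_embryo([[0, 0, 1], [0, 0, 5]], [Lineage.ICM, Lineage.ICM])
        out = ig.rescale_positions(e, 2.0)
        dz = out.nuclei[1].position[2] - out.nuclei[0].position[2]
        assert dz == pytest.approx(8.0)
        assert np.allclose(out.positions()[:, :2], e.positions()[:, :2])

    def test_rescaling_changes_graph_only_via_lengths(self):
        # two cells straddle the 30 um cutoff once z is stretched
        pos = [[0, 0, 0], [0, 0, 20], [50, 0, 0], [0, 50, 0], [50, 50, 10]]
        e = make_embryo(pos, [Lineage.ICM] * 5)
        g_before = ig.build_embryo_graph(e)
        stretched = ig.rescale_positions(e, 2.0)
        g_after = ig.build_embryo_graph(stretched)
        pair = (0, 1)  # separation 20 -> 40 um
        assert pair in g_before.edges
        assert pair not in g_after.edges

    def test_non_positive_factor_rejected(self):
        e = make_embryo([[0, 0, 0]], [Lineage.ICM])
        with pytest.raises(ValueError):
            ig.rescale_positions(e, 0.0)
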