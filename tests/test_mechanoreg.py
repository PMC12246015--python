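"""Stimulus evaluation, phenotype classification and surface summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scaffoldmech.geometry import ScaffoldSpec
from scaffoldmech.mechanoreg import (
    ConformalityError,
    Phenotype,
    StimulusConstants,
    StimulusTimeSeries,
    averaged_series,
    classify,
    classify_array,
    compare_designs,
    contribution_shares,
    find_smax,
    match_nodes,
    phenotype_map,
    phenotype_percentages,
    stimulus,
)
from scaffoldmech.synthetic_fields import FieldSeries, SurfaceMesh

CONSTS = StimulusConstants()


def _mesh(n=4, areas=None, spec=None):
    rng = np.random.default_rng(0)
    return SurfaceMesh(
        spec=spec or ScaffoldSpec(name="toy"),
        node_ids=np.arange(n),
        positions=rng.random((n, 3)),
        areas=np.asarray(areas if areas is not None else np.ones(n), dtype=float),
        junction=np.zeros(n),
    )


def _series(times, oss_vals, wss_vals, mesh):
    return (
        FieldSeries("oss", np.asarray(times, float), np.asarray(oss_vals, float), mesh),
        FieldSeries("wss", np.asarray(times, float), np.asarray(wss_vals, float), mesh),
    )


class TestStimulus:
    def test_zero_inputs(self):
        assert stimulus(0.0, 0.0) == 0.0

    def test_unit_terms(self):
        # both terms equal one by the definition of a and b
        assert stimulus(0.0375, 10.0) == pytest.approx(2.0)

    def test_reference_peak_combination(self):
        assert stimulus(0.045, 14.76) == pytest.approx(2.676)

    @settings(deadline=None, derandomize=True)
    @given(
        st.floats(0, 0.2), st.floats(0, 50), st.floats(0.01, 10)
    )
    def test_linearity(self, oss, wss, k):
        assert stimulus(k * oss, k * wss) == pytest.approx(
            k * stimulus(oss, wss), rel=1e-12, abs=1e-12
        )

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            stimulus(-0.01, 1.0)


class TestClassify:
    @pytest.mark.parametrize(
        "s, expected",
        [
            (0.005, Phenotype.VERY_LOW),
            (0.01, Phenotype.VERY_LOW),
            (0.5, Phenotype.BONE),
            (1.0, Phenotype.BONE),
            (2.0, Phenotype.CARTILAGE),
            (3.0, Phenotype.CARTILAGE),
            (4.5, Phenotype.FIBROUS),
            (6.0, Phenotype.FIBROUS),
            (6.5, Phenotype.VERY_HIGH),
        ],
    )
    def test_interval_partition(self, s, expected):
        assert classify(s) is expected

    @pytest.mark.parametrize("theta", [0.01, 1.0, 3.0, 6.0])
    def test_inclusive_upper_bounds_at_every_threshold(self, theta):
        below, above = classify(theta), classify(theta + 1e-9)
        order = list(Phenotype)
        assert order.index(above) == order.index(below) + 1

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(1)
        s = rng.uniform(0, 8, 200)
        vec = classify_array(s)
        assert all(vec[i] is classify(v) for i, v in enumerate(s))

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            classify(float("nan"))
        with pytest.raises(ValueError):
            classify_array(np.array([1.0, np.nan]))


class TestMatchNodes:
    def test_identity_for_identical_sets(self):
        pts = np.random.default_rng(2).random((50, 3))
        assert np.array_equal(match_nodes(pts, pts), np.arange(50))

    def test_tolerant_to_tiny_perturbations(self):
        rng = np.random.default_rng(3)
        pts = rng.random((50, 3))
        jitter = pts + rng.uniform(-4e-7, 4e-7, pts.shape)
        assert np.array_equal(match_nodes(pts, jitter), np.arange(50))

    def test_permuted_cloud_recovered(self):
        rng = np.random.default_rng(4)
        pts = rng.random((30, 3))
        perm = rng.permutation(30)
        mapping = match_nodes(pts, pts[perm])
        assert np.allclose(pts[perm][mapping], pts)

    def test_unmatched_node_reported(self):
        pts = np.random.default_rng(5).random((10, 3))
        other = pts.copy()
        other[7] += 0.5
        with pytest.raises(ConformalityError, match="7"):
            match_nodes(pts, other)

    def test_count_mismatch_rejected(self):
        pts = np.random.default_rng(6).random((10, 3))
        with pytest.raises(ConformalityError, match="counts"):
            match_nodes(pts, pts[:9])


class TestAveragedSeries:
    def test_wss_average_is_area_weighted(self):
        mesh = _mesh(2, areas=[1.0, 3.0])
        oss, wss = _series([0.0, 0.5, 1.0], np.zeros((3, 2)),
                           [[0, 0], [4.0, 0.0], [0, 0]], mesh)
        series = averaged_series(oss, wss)
        assert series.wss_avg[1] == pytest.approx(1.0)

    def test_oss_average_ignores_area(self):
        mesh = _mesh(2, areas=[1.0, 99.0])
        oss, wss = _series([0.0, 0.5, 1.0], [[0, 0], [0.02, 0.04], [0, 0]],
                           np.zeros((3, 2)), mesh)
        series = averaged_series(oss, wss)
        assert series.oss_avg[1] == pytest.approx(0.03)

    def test_all_zero_fields_give_flat_zero_stimulus(self):
        mesh = _mesh(3)
        oss, wss = _series([0.0, 0.5, 1.0], np.zeros((3, 3)), np.zeros((3, 3)), mesh)
        assert np.all(averaged_series(oss, wss).s_avg == 0.0)

    def test_stimulus_identity_holds_pointwise(self):
        mesh = _mesh(3)
        rng = np.random.default_rng(7)
        oss, wss = _series(
            np.linspace(0, 1, 5), rng.random((5, 3)) * 0.05, rng.random((5, 3)) * 10,
            mesh,
        )
        series = averaged_series(oss, wss)
        assert np.allclose(
            series.s_avg, series.oss_avg / CONSTS.a + series.wss_avg / CONSTS.b
        )

    def test_mismatched_time_grids_rejected(self):
        mesh = _mesh(2)
        oss, _ = _series([0.0, 0.5, 1.0], np.zeros((3, 2)), np.zeros((3, 2)), mesh)
        _, wss = _series([0.0, 0.4, 1.0], np.zeros((3, 2)), np.zeros((3, 2)), mesh)
        with pytest.raises(ValueError, match="time"):
            averaged_series(oss, wss)


def _stimulus_series(times, s_vals):
    times = np.asarray(times, float)
    s = np.asarray(s_vals, float)
    return StimulusTimeSeries(
        times=times, oss_avg=s * CONSTS.a, wss_avg=np.zeros_like(s), s_avg=s
    )


class TestFindSmax:
    def test_two_bumps_located(self):
        t = np.linspace(0, 1, 101)
        s = np.exp(-((t - 0.3) / 0.05) ** 2) + 2 * np.exp(-((t - 0.7) / 0.05) ** 2)
        (v1, t1), (v2, t2) = find_smax(_stimulus_series(t, s))
        assert t1 == pytest.approx(0.3) and t2 == pytest.approx(0.7)
        assert v2 > v1

    def test_constant_series_ties_break_late(self):
        t = np.linspace(0, 1, 101)
        (v1, t1), (v2, t2) = find_smax(_stimulus_series(t, np.ones_like(t)))
        assert v1 == v2 == 1.0
        assert t1 == pytest.approx(0.49)  # last sample before the half cycle
        assert t2 == pytest.approx(0.99)  # cycle end excluded

    def test_monotone_series_peaks_at_window_edges(self):
        t = np.linspace(0, 1, 101)
        (v1, t1), (_, t2) = find_smax(_stimulus_series(t, t.copy()))
        assert t1 == pytest.approx(0.49) and t2 == pytest.approx(0.99)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            find_smax(_stimulus_series([0.0, 0.01], [1.0, 2.0]))


class TestPhenotypeSurface:
    def test_zero_fields_map_to_very_low(self):
        mesh = _mesh(5)
        oss, wss = _series([0.0, 1.0], np.zeros((2, 5)), np.zeros((2, 5)), mesh)
        _, classes = phenotype_map(oss, wss, 1.0)
        assert all(c is Phenotype.VERY_LOW for c in classes)

    def test_uniform_unit_terms_map_to_cartilage(self):
        mesh = _mesh(4)
        oss, wss = _series(
            [0.0, 1.0], [[0] * 4, [0.0375] * 4], [[0] * 4, [10.0] * 4], mesh
        )
        s, classes = phenotype_map(oss, wss, 1.0)
        assert np.allclose(s, 2.0)
        assert all(c is Phenotype.CARTILAGE for c in classes)

    def test_absent_evaluation_time_rejected(self):
        mesh = _mesh(2)
        oss, wss = _series([0.0, 1.0], np.zeros((2, 2)), np.zeros((2, 2)), mesh)
        with pytest.raises(ValueError, match="t_eval"):
            phenotype_map(oss, wss, 0.37)

    def test_classification_is_local(self):
        mesh = _mesh(6)
        rng = np.random.default_rng(8)
        oss, wss = _series(
            [0.0, 1.0], rng.random((2, 6)) * 0.2, rng.random((2, 6)) * 40, mesh
        )
        _, full = phenotype_map(oss, wss, 1.0)
        sub_mesh = _mesh(3)
        oss_s, wss_s = _series(
            [0.0, 1.0], oss.values[:, :3], wss.values[:, :3], sub_mesh
        )
        _, sub = phenotype_map(oss_s, wss_s, 1.0)
        assert all(a is b for a, b in zip(full[:3], sub))


class TestPhenotypePercentages:
    def test_uniform_class_is_hundred_percent(self):
        classes = np.array([Phenotype.BONE] * 10, dtype=object)
        summary = phenotype_percentages(classes, np.ones(10))
        assert summary[Phenotype.BONE] == 100.0

    def test_equal_area_split(self):
        classes = np.array(
            [Phenotype.BONE] * 5 + [Phenotype.CARTILAGE] * 5, dtype=object
        )
        summary = phenotype_percentages(classes, np.ones(10))
        assert summary[Phenotype.BONE] == summary[Phenotype.CARTILAGE] == 50.0

    def test_matches_sorting_oracle_on_random_maps(self):
        # independent recomputation: sort nodes by class, sum areas
        rng = np.random.default_rng(9)
        options = list(Phenotype)
        for _ in range(500):
            n = rng.integers(3, 40)
            classes = np.array(
                [options[i] for i in rng.integers(0, 5, n)], dtype=object
            )
            areas = rng.uniform(0.1, 2.0, n)
            summary = phenotype_percentages(classes, areas)
            oracle: dict = {c: 0.0 for c in options}
            for c, a in sorted(zip(classes, areas), key=lambda p: p[0].value):
                oracle[c] += a
            for c in options:
                assert summary[c] == pytest.approx(
                    100 * oracle[c] / areas.sum(), abs=1e-9
                )
            assert sum(summary.percentages.values()) == pytest.approx(100.0)

    def test_length_mismatch_rejected(self):
        classes = np.array([Phenotype.BONE] * 3, dtype=object)
        with pytest.raises(ValueError):
            phenotype_percentages(classes, np.ones(4))


class TestCompareAndShares:
    def _summary(self, bone, cartilage):
        classes = np.array(
            [Phenotype.BONE] * bone + [Phenotype.CARTILAGE] * cartilage,
            dtype=object,
        )
        return phenotype_percentages(classes, np.ones(bone + cartilage))

    def test_identical_summaries_zero_deltas(self):
        s = self._summary(4, 6)
        assert all(v == 0.0 for v in compare_designs(s, s).values())

    def test_deltas_sum_to_zero_and_antisymmetric(self):
        a, b = self._summary(4, 6), self._summary(7, 3)
        fwd, rev = compare_designs(a, b), compare_designs(b, a)
        assert sum(fwd.values()) == pytest.approx(0.0)
        assert all(fwd[c] == -rev[c] for c in fwd)

    def test_equal_terms_split_fifty_fifty(self):
        oss_share, wss_share = contribution_shares(0.0375, 10.0)
        assert oss_share == pytest.approx(50.0)
        assert wss_share == pytest.approx(50.0)

    def test_pure_solid_stimulus(self):
        assert contribution_shares(0.05, 0.0) == (100.0, 0.0)

    def test_shares_always_sum_to_hundred(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            o, w = rng.uniform(0, 0.1), rng.uniform(0, 30)
            if o == w == 0:
                continue
            assert sum(contribution_shares(o, w)) == pytest.approx(100.0)

    def test_zero_stimulus_rejected(self):
        with pytest.raises(ZeroDivisionError):
            contribution_shares(0.0, 0.0)
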