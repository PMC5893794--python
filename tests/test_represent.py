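"""Representation separability: bin selection, PCA, distances, regression."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from gripdecode import decoder as dec
from gripdecode import represent as rep
from gripdecode.features import FeatureMatrix
from gripdecode.preprocess import BinnedCounts, SpikeTrain, bin_spike_counts
from gripdecode.synth import REST, ArrayLayout, CueSchedule

from test_decoder import _schedule, _trace


class TestSelectActiveBins:
    def test_perfect_decode_selects_full_cue_sets(self):
        sched = _schedule([("a", 1.0), (REST, 1.0), ("b", 1.0)])
        times = np.arange(30) * 0.1
        trace = _trace(times, sched.labels_for_times(times), ["a", "b"])
        sets = rep.select_active_bins(trace, sched)
        assert np.array_equal(sets["a"], np.arange(0, 10))
        assert np.array_equal(sets["b"], np.arange(20, 30))

    def test_wrong_cue_activation_excluded_from_both(self):
        """Decoder active for A during B's cue: bin in neither set."""
        sched = _schedule([("a", 1.0), ("b", 1.0)])
        times = np.arange(20) * 0.1
        states = ["a"] * 10 + ["a"] + ["b"] * 9
        trace = _trace(times, states, ["a", "b"])
        sets = rep.select_active_bins(trace, sched)
        assert 10 not in sets["a"] and 10 not in sets["b"]
        # oracle: direct set intersection of the two conditions
        cue = sched.labels_for_times(times)
        for m in ("a", "b"):
            expect = set(np.flatnonzero(
                (np.asarray(states, dtype=object) == m) & (cue == m)))
            assert set(sets[m]) == expect


class TestPca:
    def test_collinear_data_second_component_vanishes(self):
        rng = np.random.default_rng(0)
        t = rng.standard_normal(50)
        X = np.outer(t, np.ones(5)) + 0.0
        X[:, 1] *= 2
        coords, evr = rep.pca_project(X + 1e-12 * rng.standard_normal(X.shape))
        assert evr[1] < 1e-6

    def test_separated_classes_separate_in_pc_space(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((100, 96)) * 0.3
        b = rng.standard_normal((100, 96)) * 0.3 + np.r_[5.0, np.zeros(95)]
        coords, _ = rep.pca_project(np.vstack([a, b]))
        ca, cb = coords[:100].mean(0), coords[100:].mean(0)
        within = 0.5 * (coords[:100].std(0).mean() + coords[100:].std(0).mean())
        assert np.linalg.norm(ca - cb) > 3 * within

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((40, 10))
        c1, _ = rep.pca_project(X)
        c2, _ = rep.pca_project(X.copy())
        assert np.array_equal(c1, c2)

    def test_rank_deficient_rejected(self):
        X = np.tile(np.arange(5.0), (10, 1))
        with pytest.raises(rep.RepresentError):
            rep.pca_project(X)

    def test_projection_variance_bounded_by_input(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((60, 8))
        coords, _ = rep.pca_project(X)
        total_in = ((X - X.mean(0)) ** 2).sum()
        total_out = (coords**2).sum()
        assert total_out <= total_in + 1e-9


class TestClusterGaussians:
    def test_isotropic_cluster_well_conditioned(self):
        rng = np.random.default_rng(4)
        pts = rng.standard_normal((500, 2))
        out = rep.fit_cluster_gaussians(pts, np.full(500, "a", dtype=object))
        mu, cov = out["a"]
        assert np.linalg.cond(cov) < 3

    def test_near_point_mass_mean(self):
        pts = np.full((5, 2), 3.0) + 1e-9 * np.arange(10).reshape(5, 2)
        out = rep.fit_cluster_gaussians(pts, np.full(5, "a", dtype=object))
        mu, cov = out["a"]
        assert np.allclose(mu, 3.0, atol=1e-8)
        assert np.all(np.linalg.eigvalsh(cov) > 0)


class TestMeanMwpMap:
    def test_constant_field_uniform_grid(self):
        layout = ArrayLayout()
        fm = FeatureMatrix(np.arange(4) * 0.1, np.ones((4, 96)))
        grids = rep.mean_mwp_map(fm, {"a": np.arange(4)}, layout)
        g = grids["a"]
        assert np.nansum(g == 1.0) == 96
        for r, c in layout.reference_positions:
            assert np.isnan(g[r, c])

    def test_one_hot_channel_maps_to_its_grid_cell(self):
        layout = ArrayLayout()
        vals = np.zeros((3, 96))
        vals[:, 42] = 7.0
        fm = FeatureMatrix(np.arange(3) * 0.1, vals)
        g = rep.mean_mwp_map(fm, {"a": np.arange(3)}, layout)["a"]
        r, c = layout.positions[42]
        assert g[r, c] == 7.0
        assert np.nanmax(g) == g[r, c]

    def test_empty_bin_set_skipped(self):
        fm = FeatureMatrix(np.arange(3) * 0.1, np.ones((3, 96)))
        grids = rep.mean_mwp_map(fm, {"a": np.array([], int)}, ArrayLayout())
        assert grids == {}


class TestPairwiseSeparability:
    def test_identical_vectors_zero_distance(self):
        M = np.tile(np.arange(96.0), (3, 1))
        dist, agg = rep.pairwise_separability(M)
        assert np.allclose(dist.to_numpy(), 0.0)
        assert np.allclose(agg.to_numpy(), 0.0)

    def test_matches_naive_formula(self):
        rng = np.random.default_rng(5)
        M = rng.standard_normal((3, 96))
        dist, agg = rep.pairwise_separability(M)
        for i in range(3):
            for j in range(3):
                d = np.sqrt(np.sum((M[i] - M[j]) ** 2))
                assert dist.iloc[i, j] == pytest.approx(d, abs=1e-12)
            assert agg.iloc[i] == pytest.approx(
                sum(np.sqrt(np.sum((M[i] - M[j]) ** 2))
                    for j in range(3) if j != i), abs=1e-12)

    @given(hnp.arrays(float, (5, 8),
                      elements=st.floats(-100, 100, allow_nan=False)))
    @settings(max_examples=100, deadline=None)
    def test_metric_axioms(self, M):
        dist, _ = rep.pairwise_separability(M)
        D = dist.to_numpy()
        assert np.allclose(D, D.T, atol=1e-9)
        assert np.allclose(np.diag(D), 0.0, atol=1e-9)
        assert np.all(D >= -1e-9)
        for i in range(5):
            for j in range(5):
                for k in range(5):
                    assert D[i, j] <= D[i, k] + D[k, j] + 1e-9


class TestRegression:
    def test_exact_line_r2_one(self):
        acc = {"a": 90.0, "b": 95.0, "c": 100.0}
        agg = {"a": 1.0, "b": 2.0, "c": 3.0}
        res = rep.regress_accuracy_on_separability(acc, agg)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(5.0)
        assert res.n == 3

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(rep.RepresentError):
            rep.regress_accuracy_on_separability(
                {"a": 90.0, "b": 95.0, "c": 99.0},
                {"a": 1.0, "b": 1.0, "c": 1.0})

    def test_mismatched_movements_rejected(self):
        with pytest.raises(rep.RepresentError):
            rep.regress_accuracy_on_separability(
                {"a": 90.0, "b": 95.0, "c": 99.0},
                {"a": 1.0, "b": 2.0, "d": 3.0})


class TestMwpTcCorrelation:
    def test_perfect_linear_relation(self):
        rng = np.random.default_rng(6)
        n = 600
        base = rng.poisson(20, n).astype(float)
        fm = FeatureMatrix(np.arange(n) * 0.1,
                           np.tile((base / 4)[:, None], (1, 4)))
        counts = BinnedCounts(np.arange(n + 1) * 0.1, base[None, :])
        r, p = rep.correlate_mwp_tc(fm, counts)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_constant_series_rejected(self):
        fm = FeatureMatrix(np.arange(20) * 0.1, np.ones((20, 4)))
        counts = BinnedCounts(np.arange(21) * 0.1,
                              np.arange(20, dtype=float)[None, :])
        with pytest.raises(rep.RepresentError):
            rep.correlate_mwp_tc(fm, counts, window_s=2.0)

    def test_too_few_bins_rejected(self):
        fm = FeatureMatrix(np.arange(5) * 0.1, np.ones((5, 4)))
        counts = BinnedCounts(np.arange(6) * 0.1, np.ones((1, 5)))
        with pytest.raises(rep.RepresentError):
            rep.correlate_mwp_tc(fm, counts, window_s=0.5)

    def test_coupled_generator_fixture_positive_correlation(self):
        """Spikes and MWP share the modulation drive -> r > 0.5.

        Run at 15 kHz so the 1 ms spike transients are resolvable by the
        threshold-crossing detector (a spike is only ~3 samples at 3 kHz).
        """
        from gripdecode import features as feat
        from gripdecode import preprocess as pre
        from gripdecode.synth import (
            SimConfig, make_cue_schedule, generate_recording,
        )

        fs = 15_000.0
        sim = SimConfig(fs_hz=fs, seed=11)
        sched = make_cue_schedule(sim.movements, 1, seed=77)
        rec = generate_recording(sim, sched, seed=78)
        fm = feat.extract_features(rec, feat.WaveletSpec(fs_hz=fs))
        train = pre.detect_threshold_crossings(rec)
        counts = bin_spike_counts(train, rec.duration_s)
        r, p = rep.correlate_mwp_tc(fm, counts, window_s=55.0)
        assert r > 0.5
        assert p < 0.001
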