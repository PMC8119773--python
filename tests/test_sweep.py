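"""Sweep engine: subsampling, epsilon components, growth/discovery
semantics, held-out attribution and determinism."""

import numpy as np
import pytest

from cytosweep import EventMatrix, SweepConfig
from cytosweep.exceptions import ParameterError
from cytosweep.sweep import (attribute_held_out, cluster_events,
                             epsilon_components, run_sweep,
                             subsample_discovery)

from conftest import two_blob_points
from oracles import epsilon_components_bruteforce


def _matrix_two_samples(n_a, n_b, d=2, seed=0):
    rng = np.random.default_rng(seed)
    n = n_a + n_b
    return EventMatrix(
        values=rng.normal(size=(n, d)),
        channels=[f"C{i}" for i in range(d)],
        sample_id=np.array(["a"] * n_a + ["b"] * n_b, dtype=object),
        event_index=np.r_[np.arange(n_a), np.arange(n_b)],
    )


class TestSubsampleDiscovery:
    def test_constant_events_per_sample(self):
        m = _matrix_two_samples(30, 50)
        idx = subsample_discovery(m, 25, seed=3)
        sid = m.sample_id[idx]
        assert len(idx) == 50
        assert (sid == "a").sum() == 25 and (sid == "b").sum() == 25

    def test_small_samples_contribute_everything(self):
        m = _matrix_two_samples(10, 50)
        idx = subsample_discovery(m, 25, seed=3)
        assert len(idx) == 35
        assert (m.sample_id[idx] == "a").sum() == 10

    def test_deterministic_and_sorted(self):
        m = _matrix_two_samples(40, 60)
        a = subsample_discovery(m, 20, seed=9)
        b = subsample_discovery(m, 20, seed=9)
        np.testing.assert_array_equal(a, b)
        key = list(zip(m.sample_id[a].astype(str), m.event_index[a]))
        assert key == sorted(key)


class TestEpsilonComponents:
    def test_hand_examples(self):
        pts = np.array([[0.0], [1.0], [3.0]])
        comps = [list(c) for c in epsilon_components(pts, 1.5)]
        assert comps == [[0, 1], [2]]
        pts = np.array([[0.0], [1.0], [2.0], [3.0]])
        comps = [list(c) for c in epsilon_components(pts, 1.0)]
        assert comps == [[0, 1, 2, 3]]  # chaining through unit steps

    def test_diameter_distance_gives_single_component(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(40, 3))
        from scipy.spatial.distance import pdist
        d = pdist(pts).max()
        comps = epsilon_components(pts, d)
        assert len(comps) == 1 and len(comps[0]) == 40

    def test_matches_union_find_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(40):
            n = int(rng.integers(1, 90))
            dim = int(rng.integers(1, 6))
            pts = rng.random((n, dim)) * 3
            d = float(rng.random() * 1.5 + 0.05)
            mine = [list(c) for c in epsilon_components(pts, d)]
            assert mine == epsilon_components_bruteforce(pts, d)

    def test_empty_input(self):
        assert epsilon_components(np.empty((0, 3)), 1.0) == []


class TestSweepSemantics:
    def test_growth_fixed_point_before_discovery(self):
        # cluster forms from {0, .25, .5} at d=0.5 (nmin=3); then growth
        # chains 1.0 and 1.4 into it; 9.0 never joins; no second cluster
        pts = np.array([[0.0], [0.25], [0.5], [1.0], [1.4], [9.0]])
        cfg = SweepConfig(seed=0, d_min=0.5, d_max=0.5, d_step=1.0, nmin=3,
                          coverage_target=1.0)
        model = run_sweep(pts, cfg)
        assert list(model.labels) == [1, 1, 1, 1, 1, 0]
        assert model.n_clusters == 1
        assert model.stopped_by == "grid_end"

    def test_discovery_size_gate(self):
        pts = np.array([[0.0], [0.4], [0.8], [5.0]])
        cfg = SweepConfig(seed=0, d_min=0.5, d_max=0.5, d_step=1.0, nmin=3,
                          coverage_target=1.0)
        model = run_sweep(pts, cfg)
        assert list(model.labels) == [1, 1, 1, 0]

    def test_equidistant_growth_tie_goes_to_lower_cluster(self):
        # clusters at {0,1} and {10,11}; the point 5.5 is exactly 4.5 from
        # both cluster edges (events 1.0 and 10.0)
        pts = np.array([[0.0], [1.0], [10.0], [11.0], [5.5]])
        cfg = SweepConfig(seed=0, d_min=1.0, d_max=5.0, d_step=0.5, nmin=2,
                          coverage_target=1.0)
        model = run_sweep(pts, cfg)
        assert model.n_clusters == 2
        assert model.labels[4] == 1

    def test_full_hand_trace_with_coverage_stop(self):
        pts = np.array([[0.0], [0.5], [1.0], [10.0], [10.5], [11.0], [30.0]])
        cfg = SweepConfig(seed=0, d_min=1.0, d_max=25.0, d_step=1.0, nmin=3,
                          coverage_target=0.95)
        model = run_sweep(pts, cfg)
        assert model.n_clusters == 2
        assert list(model.labels) == [1, 1, 1, 2, 2, 2, 2]
        np.testing.assert_array_equal(model.creation_distance, [1.0, 1.0])
        assert model.stop_distance == 19.0  # event 30 grows in via event 11
        assert model.stopped_by == "coverage"

    def test_nmin_larger_than_n_yields_no_clusters(self):
        pts = np.random.default_rng(0).normal(size=(20, 2))
        cfg = SweepConfig(seed=0, d_min=1.0, d_max=5.0, d_step=1.0, nmin=50,
                          coverage_target=0.95)
        model = run_sweep(pts, cfg)
        assert model.n_clusters == 0
        assert np.all(model.labels == 0)
        assert model.stopped_by == "grid_end"

    def test_two_blobs_recovered(self):
        pts, truth = two_blob_points(n_per_blob=500, separation=20.0, seed=2)
        cfg = SweepConfig(seed=0, d_min=0.5, d_max=10.0, d_step=0.5, nmin=50,
                          coverage_target=0.999)
        model = run_sweep(pts, cfg)
        assert model.n_clusters == 2
        for blob in (0, 1):
            labs = model.labels[truth == blob]
            top = np.bincount(labs[labs != 0]).max()
            assert top / (truth == blob).sum() >= 0.99

    def test_empty_grid_rejected(self):
        with pytest.raises(ParameterError):
            SweepConfig(seed=0, d_min=2.0, d_max=1.0)


class TestAttribution:
    def _model(self):
        pts, _ = two_blob_points(n_per_blob=100, separation=25.0, seed=3)
        cfg = SweepConfig(seed=0, d_min=1.0, d_max=8.0, d_step=1.0, nmin=20,
                          coverage_target=0.999)
        return run_sweep(pts, cfg), pts, cfg

    def test_point_at_centroid_gets_that_cluster(self):
        model, pts, cfg = self._model()
        allp = np.vstack([pts, model.centroids[1][None, :]])
        labels = attribute_held_out(model, allp, cfg,
                                    discovery_rows=np.arange(len(pts)))
        assert labels[-1] == 2

    def test_centroid_tie_goes_to_lower_cluster(self):
        from cytosweep.sweep import ClusterModel
        model = ClusterModel(labels=np.array([1, 2]),
                             creation_distance=np.array([1.0, 1.0]),
                             centroids=np.array([[0.0, 0.0], [2.0, 2.0]]),
                             sizes=np.array([1, 1]),
                             stop_distance=1.0, stopped_by="coverage")
        pts = np.array([[0.0, 0.0], [2.0, 2.0], [1.0, 1.0]])
        cfg = SweepConfig(seed=0, d_min=1.0, d_max=1.0, nmin=2)
        labels = attribute_held_out(model, pts, cfg,
                                    discovery_rows=np.array([0, 1]))
        assert labels[2] == 1

    @pytest.mark.parametrize("mode", ["centroid", "nearest_event"])
    def test_half_held_out_blobs(self, mode):
        pts, truth = two_blob_points(n_per_blob=1000, separation=20.0,
                                     seed=4)
        rng = np.random.default_rng(5)
        disc = np.sort(rng.choice(len(pts), len(pts) // 2, replace=False))
        cfg = SweepConfig(seed=0, d_min=0.5, d_max=10.0, d_step=0.5,
                          nmin=50, coverage_target=0.999, attribution=mode)
        model = run_sweep(pts[disc], cfg)
        labels = attribute_held_out(model, pts, cfg, discovery_rows=disc)
        held = np.ones(len(pts), bool)
        held[disc] = False
        # map blob -> majority cluster on discovery events
        for blob in (0, 1):
            maj = np.bincount(
                model.labels[truth[disc] == blob]).argmax()
            mask = held & (truth == blob)
            assert (labels[mask] == maj).mean() >= 0.99

    def test_no_clusters_all_zero_with_warning(self, caplog):
        pts = np.random.default_rng(0).normal(size=(30, 2))
        cfg = SweepConfig(seed=0, d_min=0.1, d_max=0.1, d_step=1.0,
                          nmin=40, coverage_target=0.95)
        model = run_sweep(pts, cfg)
        labels = attribute_held_out(model, pts, cfg,
                                    discovery_rows=np.arange(30))
        assert np.all(labels == 0)

    def test_max_attribution_distance_gates_far_events(self):
        model, pts, cfg = self._model()
        far = pts.mean(axis=0) + 1000.0
        allp = np.vstack([pts, far[None, :]])
        gated = SweepConfig(seed=0, d_min=1.0, d_max=8.0, d_step=1.0,
                            nmin=20, coverage_target=0.999,
                            max_attribution_distance=50.0)
        labels = attribute_held_out(model, allp, gated,
                                    discovery_rows=np.arange(len(pts)))
        assert labels[-1] == 0


class TestDeterminism:
    def test_bit_identical_rerun_and_permutation_invariance(self):
        rng = np.random.default_rng(6)
        pts, truth = two_blob_points(n_per_blob=300, separation=15.0, seed=7)
        n = len(pts)
        m = EventMatrix(values=pts, channels=["a", "b"] + [f"c{i}" for i in
                                                           range(8)],
                        sample_id=np.array(["s1"] * (n // 2)
                                           + ["s2"] * (n - n // 2),
                                           dtype=object),
                        event_index=np.r_[np.arange(n // 2),
                                          np.arange(n - n // 2)])
        cfg = SweepConfig(seed=11, d_min=0.5, d_max=8.0, d_step=0.5,
                          nmin=30, coverage_target=0.98,
                          events_per_sample=200)
        model1, labels1 = cluster_events(m, cfg)
        model2, labels2 = cluster_events(m, cfg)
        np.testing.assert_array_equal(labels1, labels2)
        perm = rng.permutation(n)
        m_perm = m.subset(perm)
        _, labels3 = cluster_events(m_perm, cfg)
        np.testing.assert_array_equal(labels3, labels1[perm])
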