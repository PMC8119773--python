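"""MFI profiles, cluster assignment, quality filter and frequencies."""

import numpy as np
import pandas as pd
import pytest

from cytosweep import EventMatrix, TransformSpec, transform_channels
from cytosweep.annotate import (UNASSIGNED, assign_clusters, cluster_mfi,
                                frequency_matrix, population_mfi,
                                quality_filter)
from cytosweep.exceptions import DimensionError, ParameterError


def _matrix(values, labels=None, channels=None, sample=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    channels = channels or [f"C{i}" for i in range(values.shape[1])]
    n = len(values)
    return EventMatrix(
        values=values, channels=channels,
        sample_id=np.asarray(sample if sample is not None
                             else ["s"] * n, dtype=object),
        event_index=np.arange(n),
        manual_label=None if labels is None
        else np.asarray(labels, dtype=object))


class TestClusterMFI:
    def test_mean_of_two_events(self):
        m = _matrix([[100.0], [300.0]], channels=["CD4"])
        mfi = cluster_mfi(m, [1, 1])
        assert mfi.loc[mfi.cluster_id == 1, "CD4"].item() == 200.0

    def test_identical_events_give_their_vector(self):
        m = _matrix([[5.0, 7.0]] * 4)
        mfi = cluster_mfi(m, [2] * 4)
        assert mfi[["C0", "C1"]].to_numpy().tolist() == [[5.0, 7.0]]

    def test_mfi_on_raw_scale_after_transform(self):
        rng = np.random.default_rng(0)
        mu = np.array([2000.0, 150.0])
        vals = rng.normal(mu, [300.0, 30.0], size=(5000, 2))
        vals = np.abs(vals)
        m = transform_channels(_matrix(vals), TransformSpec())
        mfi = cluster_mfi(m, np.ones(5000, int))
        got = mfi[["C0", "C1"]].to_numpy().ravel()
        se = np.array([300.0, 30.0]) / np.sqrt(5000)
        assert np.all(np.abs(got - mu) <= 3 * se + 1.0)

    def test_misaligned_labels_raise(self):
        m = _matrix([[1.0], [2.0]])
        with pytest.raises(DimensionError):
            cluster_mfi(m, [1])


class TestAssignClusters:
    def test_majority_vote_with_purity(self):
        labels = np.ones(100, int)
        ref = np.array(["CD4"] * 90 + ["CD8"] * 10)
        a = assign_clusters(labels, ref)
        assert a.population.item() == "CD4"
        assert a.purity.item() == pytest.approx(0.90)

    def test_below_threshold_is_unassigned(self):
        labels = np.ones(100, int)
        ref = np.array(["CD4"] * 40 + ["CD8"] * 35 + ["ungated"] * 25)
        a = assign_clusters(labels, ref)
        assert a.population.item() == UNASSIGNED
        assert a.purity.item() == pytest.approx(0.40)

    def test_ungated_winner_is_unassigned(self):
        labels = np.ones(10, int)
        ref = np.array(["ungated"] * 9 + ["CD4"])
        a = assign_clusters(labels, ref)
        assert a.population.item() == UNASSIGNED

    def test_modes_agree_on_separable_clusters(self):
        rng = np.random.default_rng(1)
        centers = {"A": 10.0, "B": 50.0, "C": 90.0}
        vals, labs, ref = [], [], []
        for k, (name, c) in enumerate(centers.items(), start=1):
            block = rng.normal(c, 2.0, (300, 3))
            vals.append(block)
            labs += [k] * 300
            ref += [name] * 300
        m = _matrix(np.vstack(vals))
        labs = np.array(labs)
        ref = np.array(ref, dtype=object)
        m.manual_label = ref
        vote = assign_clusters(labs, ref)
        mfi = cluster_mfi(m, labs)
        pops = population_mfi(m)
        near = assign_clusters(labs, mode="mfi_nearest", mfi_profiles=mfi,
                               reference_profiles=pops,
                               channels=m.channels)
        assert (vote.purity == 1.0).all()
        merged = vote.merge(near, on="cluster_id", suffixes=("_v", "_n"))
        assert (merged.population_v == merged.population_n).all()

    def test_purity_invariant_under_relabeling_and_permutation(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(1, 4, 500)
        ref = np.array(rng.choice(["x", "y", "z"], 500), dtype=object)
        base = assign_clusters(labels, ref).set_index("cluster_id")
        perm = rng.permutation(500)
        permuted = assign_clusters(labels[perm], ref[perm]
                                   ).set_index("cluster_id")
        pd.testing.assert_frame_equal(base, permuted)
        remap = {1: 7, 2: 5, 3: 9}
        relabeled = assign_clusters(
            np.array([remap[v] for v in labels]), ref)
        for old, new in remap.items():
            assert (relabeled.set_index("cluster_id").loc[new, "purity"]
                    == base.loc[old, "purity"])

    def test_mfi_nearest_requires_profiles(self):
        with pytest.raises(ParameterError):
            assign_clusters(np.ones(5, int), mode="mfi_nearest")


class TestQualityFilter:
    def test_small_cluster_auto_passes_with_flag(self):
        m = _matrix(np.random.default_rng(0).normal(size=(5, 2)))
        qr = quality_filter(m, np.ones(5, int))
        row = qr.clusters.iloc[0]
        assert row.good_quality and row.auto_pass

    def test_merged_populations_fail_on_the_split_channel(self):
        rng = np.random.default_rng(3)
        a = rng.normal(50, 5, (800, 3))
        b = rng.normal(50, 5, (800, 3))
        a[:, 1] = rng.normal(10, 7, 800)
        b[:, 1] = rng.normal(80, 7, 800)
        m = _matrix(np.vstack([a, b]))
        qr = quality_filter(m, np.ones(1600, int))
        assert not qr.clusters.good_quality.item()
        assert qr.clusters.worst_channel.item() == "C1"

    def test_single_gaussian_cluster_passes(self):
        rng = np.random.default_rng(4)
        m = _matrix(rng.normal(40, 5, (2000, 4)))
        qr = quality_filter(m, np.ones(2000, int))
        assert qr.clusters.good_quality.item()


class TestFrequencyMatrix:
    def test_simple_counting(self):
        fm = frequency_matrix([1, 1, 2, 0], ["s"] * 4)
        col = fm.fractions["s"]
        assert col.loc[0] == 0.25 and col.loc[1] == 0.5 and col.loc[2] == 0.25

    def test_grouping_aggregates_and_conserves(self):
        grouping = pd.DataFrame({"cluster_id": [1, 2],
                                 "population": ["CD4", "CD4"]})
        fm = frequency_matrix([1, 1, 2, 0], ["s"] * 4, grouping=grouping)
        assert fm.fractions.loc["CD4", "s"] == 0.75
        assert fm.fractions.loc["cluster_0", "s"] == 0.25
        assert fm.counts["s"].sum() == 4

    def test_columns_sum_to_one_and_grouping_preserves_column_sums(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 6, 5000)
        samples = rng.choice(["a", "b", "c"], 5000)
        fm = frequency_matrix(labels, samples)
        np.testing.assert_allclose(fm.fractions.sum(axis=0), 1.0,
                                   atol=1e-9)
        grouping = pd.DataFrame({"cluster_id": [1, 2, 3, 4, 5],
                                 "population": ["p", "p", "q", UNASSIGNED,
                                                "q"]})
        fg = frequency_matrix(labels, samples, grouping=grouping)
        np.testing.assert_allclose(fg.fractions.sum(axis=0), 1.0,
                                   atol=1e-9)
        pd.testing.assert_series_equal(fg.counts.sum(axis=0),
                                       fm.counts.sum(axis=0))
        for s in "abc":
            assert fm.counts[s].sum() == (samples == s).sum()
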