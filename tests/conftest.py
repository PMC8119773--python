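"""Shared fixtures: synthetic cohorts and the large shared clustering run.

Everything is generated programmatically with fixed seeds; the expensive
cohort-scale run is session-scoped and shared by the acceptance tests.
"""

import numpy as np
import pytest

from cytosweep import (SweepConfig, TransformSpec, default_population_spec,
                       generate_cohort, run_sweep, subsample_discovery,
                       transform_channels)

BIG_SEED = 12345


@pytest.fixture(scope="session")
def small_cohort():
    """A fast 4-sample default-abundance cohort (raw scale)."""
    spec = default_population_spec(seed=101, n_samples=4,
                                   events_per_sample_range=(3000, 5000))
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_cohort_transformed(small_cohort):
    return transform_channels(small_cohort, TransformSpec())


@pytest.fixture(scope="session")
def cohort_run():
    """The cohort-scale shared run: 20 samples x 30000-60000 events,
    discovery at 5000 events/sample, sweeps at nmin 20 and nmin 60."""
    spec = default_population_spec(
        seed=BIG_SEED, n_samples=20, events_per_sample_range=(30000, 60000))
    m = generate_cohort(spec)
    mt = transform_channels(m, TransformSpec())
    canon = mt.subset(mt.canonical_order())
    disc = subsample_discovery(canon, 5000, BIG_SEED)
    model20 = run_sweep(canon.values[disc],
                        SweepConfig(seed=BIG_SEED, nmin=20,
                                    events_per_sample=5000))
    model20.discovery_indices = disc
    model60 = run_sweep(canon.values[disc],
                        SweepConfig(seed=BIG_SEED, nmin=60,
                                    events_per_sample=5000))
    model60.discovery_indices = disc
    return {"matrix": canon, "discovery": disc,
            "model20": model20, "model60": model60,
            "config": SweepConfig(seed=BIG_SEED, nmin=20,
                                  events_per_sample=5000)}


def two_blob_points(n_per_blob=500, d=10, separation=20.0, seed=0):
    """Two well-separated Gaussian blobs with ground-truth labels."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, (n_per_blob, d))
    b = rng.normal(0.0, 1.0, (n_per_blob, d))
    b[:, 0] += separation
    pts = np.vstack([a, b])
    truth = np.repeat([0, 1], n_per_blob)
    return pts, truth
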