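"""The density-sweep clustering engine.

The algorithm runs over an increasing grid of Euclidean distance cut-offs.
At each cut-off d, two phases happen in order:

* **Growth** — iterated to a fixed point, every still-unattributed discovery
  event within distance d of an attributed event joins the cluster of its
  nearest attributed event (ties go to the lower cluster id).  Existing
  clusters never merge and events never change a non-zero label, so early
  (high-density) clusters keep their identity throughout the sweep.
* **Discovery** — the remaining unattributed events are partitioned into
  connected components of the <=d distance graph; every component with at
  least ``nmin`` members becomes a new cluster, numbered after all existing
  ones.

The sweep stops at the first grid level where the attributed fraction
(coverage) reaches ``coverage_target``, or at the end of the grid.  Events
never attributed stay in the reserved cluster 0.  Discovery runs on a
per-sample subsample (constant events per sample) so every sample
contributes equally; all remaining events are attributed afterwards to the
closest discovered cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components as _cc
from scipy.spatial import cKDTree

from .exceptions import DimensionError, ParameterError
from .io import EventMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SweepConfig:
    """All parameters of a clustering run.

    The distance grid (``d_min``, ``d_min + d_step``, ..., <= ``d_max``) is
    expressed in clustering-space units; with the default arcsinh +
    [0, 100] per-channel rescaling a unit increment is a meaningful
    resolution step.  ``nmin`` is the minimum number of events an
    epsilon-component needs to be retained as a new cluster — the density
    gate.  ``seed`` drives the only stochastic step (discovery
    subsampling) and is mandatory.
    """

    seed: int
    d_min: float = 1.0
    d_max: float = 50.0
    d_step: float = 1.0
    nmin: int = 40
    coverage_target: float = 0.95
    events_per_sample: int = 25000
    attribution: str = "centroid"
    max_attribution_distance: float | None = None

    def __post_init__(self):
        if not (self.d_min > 0 and self.d_step > 0
                and self.d_max >= self.d_min):
            raise ParameterError(
                "need 0 < d_min <= d_max and d_step > 0")
        if not 0.0 < self.coverage_target <= 1.0:
            raise ParameterError("coverage_target must be in (0, 1]")
        if self.nmin < 1:
            raise ParameterError("nmin must be a positive integer")
        if self.events_per_sample < 1:
            raise ParameterError("events_per_sample must be >= 1")
        if self.attribution not in ("centroid", "nearest_event"):
            raise ParameterError(
                f"unknown attribution mode {self.attribution!r}")

    @property
    def grid(self) -> np.ndarray:
        n = int(np.floor((self.d_max - self.d_min) / self.d_step + 1e-9)) + 1
        return self.d_min + self.d_step * np.arange(n)


@dataclass
class ClusterModel:
    """Result of the discovery-phase sweep.

    ``labels`` holds one integer per discovery event: 1..K for clusters in
    order of creation, 0 for never-attributed events.  ``creation_distance``
    is the grid value at which each cluster appeared (non-decreasing in
    cluster id); ``centroids`` are arithmetic means in clustering space
    after the final level.
    """

    labels: np.ndarray
    creation_distance: np.ndarray
    centroids: np.ndarray
    sizes: np.ndarray
    stop_distance: float
    stopped_by: str
    discovery_indices: np.ndarray = field(default_factory=lambda: np.array([], int))
    trace: list = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.creation_distance)

    @property
    def coverage(self) -> float:
        return float(np.mean(self.labels != 0)) if len(self.labels) else 0.0

    def summary_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "cluster_id": np.arange(1, self.n_clusters + 1),
            "size": self.sizes,
            "creation_distance": self.creation_distance,
            **{f"centroid_{j}": self.centroids[:, j]
               for j in range(self.centroids.shape[1])},
        })


# ---------------------------------------------------------------------------
# Discovery subsampling
# ---------------------------------------------------------------------------

def subsample_discovery(m: EventMatrix, events_per_sample: int,
                        seed: int) -> np.ndarray:
    """Row indices of the discovery set: a constant-size draw per sample.

    For each sample (processed in sorted name order), exactly
    ``min(events_per_sample, sample size)`` events are drawn uniformly
    without replacement; the result is sorted by (sample_id, event_index),
    so it is invariant under permutation of the input rows.
    """
    if m.n_events == 0:
        raise ParameterError("empty event matrix")
    rng = np.random.default_rng(seed)
    sid = m.sample_id.astype(str)
    chosen = []
    for s in sorted(set(sid)):
        rows = np.where(sid == s)[0]
        rows = rows[np.argsort(m.event_index[rows], kind="stable")]
        if len(rows) <= events_per_sample:
            if len(rows) < events_per_sample:
                logger.warning(
                    "sample %s has %d events (< quota %d); using all",
                    s, len(rows), events_per_sample)
            take = rows
        else:
            take = rows[rng.choice(len(rows), events_per_sample,
                                   replace=False)]
        chosen.append(take)
    idx = np.concatenate(chosen)
    order = np.lexsort((m.event_index[idx], sid[idx]))
    return idx[order]


# ---------------------------------------------------------------------------
# Epsilon components
# ---------------------------------------------------------------------------

def epsilon_components(points, d: float) -> list[np.ndarray]:
    """Connected components of the <=d Euclidean-distance graph.

    Two points share a component iff a chain of points links them with
    consecutive distances <= d.  Components are ordered by decreasing size,
    ties broken by the smallest contained row index; each component's
    indices are sorted.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2:
        raise DimensionError("points must be 2-D")
    n = pts.shape[0]
    if n == 0:
        return []
    if d <= 0:
        raise ParameterError("d must be positive")
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=d, output_type="ndarray")
    if len(pairs):
        g = sparse.coo_matrix(
            (np.ones(len(pairs), dtype=np.int8), (pairs[:, 0], pairs[:, 1])),
            shape=(n, n))
        _, lab = _cc(g, directed=False)
    else:
        lab = np.arange(n)
    order = np.argsort(lab, kind="stable")
    sizes = np.bincount(lab)
    bounds = np.cumsum(sizes)
    comps = [order[s:e] for s, e in zip(np.r_[0, bounds[:-1]], bounds)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return [np.sort(c) for c in comps]


# ---------------------------------------------------------------------------
# Sweep
# ---------------------------------------------------------------------------

def _nearest_labeled(batch_points, batch_labels, query_points):
    """Distance and label of the nearest batch point for each query point.

    Exact ties between batch points are resolved toward the lower cluster
    label (checked across the 4 nearest neighbours, which covers any
    realistic tie multiplicity).
    """
    tree = cKDTree(batch_points)
    k = min(len(batch_points), 4)
    dist, idx = tree.query(query_points, k=k)
    if k == 1:
        return dist.ravel(), batch_labels[idx.ravel()]
    dmin = dist[:, 0]
    labs = batch_labels[idx]
    tied = dist <= dmin[:, None]
    labs = np.where(tied, labs, np.iinfo(np.int64).max)
    return dmin, labs.min(axis=1)


class _SweepState:
    """Mutable discovery-phase state shared by the per-level steps."""

    def __init__(self, points, nmin):
        self.points = np.ascontiguousarray(points, dtype=np.float64)
        self.n = self.points.shape[0]
        self.nmin = int(nmin)
        self.labels = np.zeros(self.n, dtype=np.int64)
        self.creation_distance: list[float] = []
        # nearest-attributed-event cache for unattributed events
        self.nad_dist = np.full(self.n, np.inf)
        self.nad_label = np.zeros(self.n, dtype=np.int64)

    @property
    def n_clusters(self):
        return len(self.creation_distance)

    def _refresh_cache(self, new_idx):
        """Fold newly attributed events into the nearest-attributed cache."""
        rem = np.where(self.labels == 0)[0]
        if len(rem) == 0 or len(new_idx) == 0:
            return
        dist, lab = _nearest_labeled(self.points[new_idx],
                                     self.labels[new_idx],
                                     self.points[rem])
        better = (dist < self.nad_dist[rem]) | (
            (dist == self.nad_dist[rem]) & (lab < self.nad_label[rem]))
        upd = rem[better]
        self.nad_dist[upd] = dist[better]
        self.nad_label[upd] = lab[better]

    def step(self, d: float):
        """One grid level: growth to a fixed point, then discovery."""
        # -- growth --
        while True:
            join = np.where((self.labels == 0) & (self.nad_dist <= d))[0]
            if len(join) == 0:
                break
            self.labels[join] = self.nad_label[join]
            self._refresh_cache(join)
        # -- discovery --
        rem = np.where(self.labels == 0)[0]
        if len(rem):
            newly = []
            for comp in epsilon_components(self.points[rem], d):
                if len(comp) >= self.nmin:
                    cid = self.n_clusters + 1
                    rows = rem[comp]
                    self.labels[rows] = cid
                    self.creation_distance.append(float(d))
                    newly.append(rows)
            if newly:
                self._refresh_cache(np.concatenate(newly))

    @property
    def coverage(self):
        return float(np.mean(self.labels != 0)) if self.n else 0.0


def run_sweep(points, config: SweepConfig,
              keep_trace: bool = False) -> ClusterModel:
    """Run the full increasing-distance sweep over the discovery points.

    Deterministic given ``points`` and ``config``.  Stops at the first grid
    level whose post-step coverage reaches ``config.coverage_target``
    (``stopped_by == "coverage"``), else at the end of the grid
    (``stopped_by == "grid_end"``).  With ``keep_trace`` the model records,
    for every processed level, the distance, a copy of the labels and the
    coverage after the step (for audit; memory grows with n x levels).
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[0] == 0:
        raise ParameterError("points must be a non-empty 2-D array")
    grid = config.grid
    if len(grid) == 0:
        raise ParameterError("empty distance grid")
    state = _SweepState(pts, config.nmin)
    trace = []
    stop_distance = grid[-1]
    stopped_by = "grid_end"
    for d in grid:
        state.step(float(d))
        if keep_trace:
            trace.append({"d": float(d), "labels": state.labels.copy(),
                          "coverage": state.coverage,
                          "sizes": np.bincount(state.labels)[1:].copy()})
        if state.coverage >= config.coverage_target:
            stop_distance = float(d)
            stopped_by = "coverage"
            break
    K = state.n_clusters
    centroids = np.zeros((K, pts.shape[1]))
    sizes = np.zeros(K, dtype=np.int64)
    for k in range(1, K + 1):
        mask = state.labels == k
        sizes[k - 1] = int(mask.sum())
        centroids[k - 1] = pts[mask].mean(axis=0)
    return ClusterModel(labels=state.labels,
                        creation_distance=np.array(state.creation_distance),
                        centroids=centroids, sizes=sizes,
                        stop_distance=float(stop_distance),
                        stopped_by=stopped_by, trace=trace)


def attribute_held_out(model: ClusterModel, all_points,
                       config: SweepConfig,
                       discovery_rows=None) -> np.ndarray:
    """Labels for the full event set.

    Discovery events keep their sweep labels (including 0); every other
    event is attributed to the closest discovered cluster — by centroid
    distance (default) or by distance to the nearest attributed discovery
    event (``attribution="nearest_event"``).  If
    ``config.max_attribution_distance`` is set, events farther than that
    from every cluster stay in cluster 0.  Ties go to the lower cluster id.
    """
    pts = np.asarray(all_points, dtype=np.float64)
    n = pts.shape[0]
    labels = np.zeros(n, dtype=np.int64)
    if discovery_rows is None:
        discovery_rows = model.discovery_indices
    discovery_rows = np.asarray(discovery_rows, dtype=np.int64)
    labels[discovery_rows] = model.labels
    if model.n_clusters == 0:
        logger.warning("no clusters discovered; all events in cluster 0")
        return labels
    held = np.ones(n, dtype=bool)
    held[discovery_rows] = False
    held_rows = np.where(held)[0]
    if len(held_rows) == 0:
        return labels
    if config.attribution == "centroid":
        # chunked exact nearest centroid; ties resolve to the lower id
        # because argmin returns the first minimum
        from scipy.spatial.distance import cdist
        best_d = np.full(len(held_rows), np.inf)
        best_k = np.zeros(len(held_rows), dtype=np.int64)
        chunk = 100_000
        for s in range(0, len(held_rows), chunk):
            rows = held_rows[s:s + chunk]
            dm = cdist(pts[rows], model.centroids)
            am = np.argmin(dm, axis=1)
            best_k[s:s + chunk] = am + 1
            best_d[s:s + chunk] = dm[np.arange(len(rows)), am]
    else:
        attributed = model.labels != 0
        dist, lab = _nearest_labeled(
            pts[discovery_rows[attributed]],
            model.labels[attributed],
            pts[held_rows])
        best_d, best_k = dist, lab
    if config.max_attribution_distance is not None:
        best_k = np.where(best_d <= config.max_attribution_distance,
                          best_k, 0)
    labels[held_rows] = best_k
    return labels


def cluster_events(m: EventMatrix, config: SweepConfig
                   ) -> tuple[ClusterModel, np.ndarray]:
    """End-to-end clustering of a (transformed) event matrix.

    Subsamples the discovery set at constant events per sample, runs the
    sweep, attributes held-out events, and returns the model plus per-event
    labels aligned to the rows of ``m``.  The result is invariant under
    permutation of input rows (labels follow the rows).
    """
    order = m.canonical_order()
    canon = m.subset(order)
    disc = subsample_discovery(canon, config.events_per_sample, config.seed)
    model = run_sweep(canon.values[disc], config)
    model.discovery_indices = disc
    labels_canon = attribute_held_out(model, canon.values, config,
                                      discovery_rows=disc)
    labels = np.empty(m.n_events, dtype=np.int64)
    labels[order] = labels_canon
    return model, labels


__all__ = ["SweepConfig", "ClusterModel", "subsample_discovery",
           "epsilon_components", "run_sweep", "attribute_held_out",
           "cluster_events"]
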