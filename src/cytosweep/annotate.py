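"""Cluster interpretation: MFI profiles, reference-population assignment,
unimodality quality control and cohort frequency matrices.

Clusters coming out of the sweep are anonymous.  This module turns them
into interpreted results: per-cluster mean fluorescence intensities (MFI,
always on the raw scale), assignment of each cluster to a manually gated
reference population (by event-label majority vote, or by nearest z-scored
MFI profile when no per-event labels exist), a per-channel dip-test screen
that flags clusters straddling two populations, and cluster x sample
frequency tables with optional meta-cluster grouping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dip import InsufficientDataError, dip_unimodality
from .exceptions import DimensionError, ParameterError
from .io import EventMatrix, RESERVED_UNGATED

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"
CLUSTER0_ROW = "cluster_0"


def cluster_mfi(m: EventMatrix, labels) -> pd.DataFrame:
    """Per-cluster, per-channel mean fluorescence intensity (raw scale).

    Returns one row per non-empty cluster (cluster 0 included and flagged
    by the ``unattributed`` column), channels as columns.
    """
    labels = np.asarray(labels)
    if len(labels) != m.n_events:
        raise DimensionError(
            f"{len(labels)} labels for {m.n_events} events")
    raw = m.raw
    out = []
    for k in np.unique(labels):
        mask = labels == k
        row = {"cluster_id": int(k), "n_events": int(mask.sum()),
               "unattributed": bool(k == 0)}
        means = raw[mask].mean(axis=0)
        row.update({c: float(v) for c, v in zip(m.channels, means)})
        out.append(row)
    return pd.DataFrame(out)


def population_mfi(m: EventMatrix, reference=None) -> pd.DataFrame:
    """Raw-scale MFI profile of each manually gated reference population."""
    if reference is None:
        reference = m.manual_label
    if reference is None:
        raise ParameterError("no reference labels available")
    reference = np.asarray(reference, dtype=object)
    out = []
    for name in sorted(set(reference.astype(str))):
        if name == RESERVED_UNGATED:
            continue
        mask = reference.astype(str) == name
        means = m.raw[mask].mean(axis=0)
        row = {"population": name, "n_events": int(mask.sum())}
        row.update({c: float(v) for c, v in zip(m.channels, means)})
        out.append(row)
    return pd.DataFrame(out)


def assign_clusters(labels, reference=None, mode: str = "label_vote",
                    purity_threshold: float = 0.5,
                    mfi_profiles: pd.DataFrame | None = None,
                    reference_profiles: pd.DataFrame | None = None,
                    channels: list[str] | None = None) -> pd.DataFrame:
    """Assign each discovered cluster to a reference population.

    ``label_vote`` takes the modal manual label among a cluster's events;
    the cluster is assigned iff that winner is a real population (not
    "ungated") and its share (purity) reaches ``purity_threshold``.
    ``mfi_nearest`` z-scores cluster and reference MFI profiles per channel
    (pooled statistics) and assigns each cluster to the population with the
    closest profile; it never returns "unassigned".  Ties break toward the
    lexicographically smallest population name.  Cluster 0 is never
    assigned.
    """
    labels = np.asarray(labels)
    cluster_ids = sorted(int(k) for k in np.unique(labels) if k != 0)
    rows = []
    if mode == "label_vote":
        if reference is None:
            raise ParameterError("label_vote requires per-event reference "
                                 "labels")
        reference = np.asarray(reference, dtype=object).astype(str)
        if len(reference) != len(labels):
            raise DimensionError("reference labels misaligned with labels")
        for k in cluster_ids:
            mask = labels == k
            names, counts = np.unique(reference[mask], return_counts=True)
            order = np.lexsort((names, -counts))
            winner = names[order[0]]
            purity = counts[order[0]] / mask.sum()
            pop = (winner if winner != RESERVED_UNGATED
                   and purity >= purity_threshold else UNASSIGNED)
            rows.append({"cluster_id": k, "population": pop,
                         "purity": float(purity), "mode": mode,
                         "winner": winner})
    elif mode == "mfi_nearest":
        if mfi_profiles is None or reference_profiles is None:
            raise ParameterError(
                "mfi_nearest requires cluster and reference MFI profiles")
        if channels is None:
            channels = [c for c in reference_profiles.columns
                        if c not in ("population", "n_events")]
        cl = mfi_profiles[mfi_profiles["cluster_id"] != 0]
        cmat = cl[channels].to_numpy(dtype=float)
        rmat = reference_profiles[channels].to_numpy(dtype=float)
        pooled = np.vstack([cmat, rmat])
        mu = pooled.mean(axis=0)
        sd = pooled.std(axis=0)
        sd[sd == 0] = 1.0
        cz = (cmat - mu) / sd
        rz = (rmat - mu) / sd
        names = reference_profiles["population"].to_numpy()
        name_order = np.argsort(names)  # lexicographic tie-break
        for i, k in enumerate(cl["cluster_id"].astype(int)):
            dists = np.linalg.norm(cz[i] - rz, axis=1)
            best = name_order[np.argmin(dists[name_order])]
            rows.append({"cluster_id": int(k),
                         "population": str(names[best]),
                         "purity": np.nan, "mode": mode,
                         "winner": str(names[best])})
    else:
        raise ParameterError(f"unknown assignment mode {mode!r}")
    return pd.DataFrame(rows, columns=["cluster_id", "population", "purity",
                                       "mode", "winner"])


@dataclass
class QualityReport:
    """Dip-test screen: per-channel tests and per-cluster verdicts."""

    channel_tests: pd.DataFrame   # cluster_id, channel, dip, p
    clusters: pd.DataFrame        # cluster_id, n_events, min_p, good_quality
    alpha: float

    @property
    def good_clusters(self) -> list[int]:
        ok = self.clusters[self.clusters["good_quality"]]
        return [int(k) for k in ok["cluster_id"]]


def quality_filter(m: EventMatrix, labels, alpha: float = 0.05,
                   method: str = "table") -> QualityReport:
    """Per-channel dip test of every cluster's intensity distributions.

    A cluster is good quality iff no channel rejects unimodality at level
    ``alpha`` with Bonferroni correction across channels.  The test runs on
    the clustering-space (transformed) values.  Clusters smaller than 8
    events cannot be tested and auto-pass with a flag.
    """
    labels = np.asarray(labels)
    if len(labels) != m.n_events:
        raise DimensionError("labels misaligned with event matrix")
    x = m.values
    n_ch = m.n_channels
    tests, verdicts = [], []
    for k in sorted(int(v) for v in np.unique(labels) if v != 0):
        mask = labels == k
        n_k = int(mask.sum())
        if n_k < 8:
            logger.warning("cluster %d has %d events; dip test skipped "
                           "(auto-pass)", k, n_k)
            verdicts.append({"cluster_id": k, "n_events": n_k,
                             "min_p": np.nan, "worst_channel": "",
                             "good_quality": True, "auto_pass": True})
            continue
        min_p, worst = np.inf, ""
        for j, ch in enumerate(m.channels):
            try:
                stat, p = dip_unimodality(x[mask, j], method=method)
            except InsufficientDataError:  # pragma: no cover
                stat, p = np.nan, 1.0
            tests.append({"cluster_id": k, "channel": ch,
                          "dip": stat, "p": p})
            if p < min_p:
                min_p, worst = p, ch
        verdicts.append({"cluster_id": k, "n_events": n_k,
                         "min_p": float(min_p), "worst_channel": worst,
                         "good_quality": bool(min_p >= alpha / n_ch),
                         "auto_pass": False})
    return QualityReport(
        channel_tests=pd.DataFrame(tests,
                                   columns=["cluster_id", "channel",
                                            "dip", "p"]),
        clusters=pd.DataFrame(verdicts,
                              columns=["cluster_id", "n_events", "min_p",
                                       "worst_channel", "good_quality",
                                       "auto_pass"]),
        alpha=alpha)


@dataclass
class FrequencyMatrix:
    """Cluster (or population) x sample composition tables.

    ``fractions`` columns each sum to 1 over all rows — cluster 0 (or its
    grouped ``cluster_0`` row) is part of the denominator, so entries read
    as "fraction of all analysed events of that sample".
    """

    fractions: pd.DataFrame
    counts: pd.DataFrame

    def to_csv(self, frac_path, counts_path=None, sep=","):
        self.fractions.to_csv(frac_path, sep=sep)
        if counts_path is not None:
            self.counts.to_csv(counts_path, sep=sep)


def frequency_matrix(labels, sample_id,
                     grouping: pd.DataFrame | None = None) -> FrequencyMatrix:
    """Per-sample cluster composition, optionally grouped into populations.

    Without grouping, rows are cluster ids (0 included).  With a grouping
    (an assignment table with ``cluster_id`` and ``population`` columns),
    clusters are pooled into their assigned populations; "unassigned"
    clusters are pooled under that name and cluster 0 is kept as its own
    ``cluster_0`` row, so column sums are unchanged by grouping.
    """
    labels = np.asarray(labels)
    sample_id = np.asarray(sample_id).astype(str)
    if len(labels) != len(sample_id):
        raise DimensionError("labels misaligned with sample ids")
    df = pd.DataFrame({"cluster": labels, "sample": sample_id})
    counts = (df.groupby(["cluster", "sample"]).size()
              .unstack(fill_value=0).sort_index())
    counts.columns.name = None
    if grouping is not None:
        pop_of = {int(r.cluster_id): str(r.population)
                  for r in grouping.itertuples()}
        rows = [CLUSTER0_ROW if k == 0 else pop_of.get(int(k), UNASSIGNED)
                for k in counts.index]
        counts = counts.groupby(rows).sum().sort_index()
        counts.index.name = "population"
    else:
        counts.index.name = "cluster_id"
    fractions = counts / counts.sum(axis=0)
    return FrequencyMatrix(fractions=fractions, counts=counts)


__all__ = ["cluster_mfi", "population_mfi", "assign_clusters",
           "quality_filter", "QualityReport", "frequency_matrix",
           "FrequencyMatrix", "UNASSIGNED", "CLUSTER0_ROW"]
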