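"""Event-matrix loading, channel transforms and canonical table output.

The canonical in-memory container is :class:`EventMatrix`: one row per
cytometry event, one column per fluorescence channel, with a per-event
sample identifier and a stable within-sample event index.  Loaders accept
FCS list-mode files or delimited text; rows containing non-finite values
are dropped and counted.  Pre-gating (debris/doublet/dead-cell removal) is
assumed to have happened upstream.

Clustering operates on a transformed copy of the intensities (arcsinh
compression followed by per-channel rescaling to [0, 100] by default) while
the raw intensities are retained for MFI reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (DimensionError, EmptyInputError, FormatError,
                         ParameterError)
from .fcs import read_fcs, write_fcs

logger = logging.getLogger(__name__)

RESERVED_UNGATED = "ungated"


@dataclass
class EventMatrix:
    """Events x channels intensity matrix with per-event annotations.

    Attributes
    ----------
    values
        Float intensities, shape ``(n_events, n_channels)``.  After
        :func:`transform_channels` these are in clustering space and the
        originals live in ``raw_values``.
    channels
        Ordered unique channel names.
    sample_id
        Per-event sample identifier (string array).
    event_index
        Stable 0-based original ordering within each sample.
    manual_label
        Optional per-event reference-population name (``None`` if absent).
    raw_values
        Untransformed intensities (``None`` until a transform is applied;
        :attr:`raw` always resolves to the raw scale).
    n_dropped
        Rows removed at load time because they contained NaN/Inf.
    """

    values: np.ndarray
    channels: list[str]
    sample_id: np.ndarray
    event_index: np.ndarray
    manual_label: np.ndarray | None = None
    raw_values: np.ndarray | None = None
    n_dropped: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise DimensionError("values must be a 2-D events x channels array")
        n = self.values.shape[0]
        self.channels = [str(c) for c in self.channels]
        if len(self.channels) != self.values.shape[1]:
            raise DimensionError(
                f"{len(self.channels)} channel names for "
                f"{self.values.shape[1]} columns")
        if len(set(self.channels)) != len(self.channels):
            raise FormatError("channel names must be unique")
        self.sample_id = np.asarray(self.sample_id, dtype=object)
        self.event_index = np.asarray(self.event_index, dtype=np.int64)
        if len(self.sample_id) != n or len(self.event_index) != n:
            raise DimensionError(
                "sample_id/event_index length does not match event count")
        if self.manual_label is not None:
            self.manual_label = np.asarray(self.manual_label, dtype=object)
            if len(self.manual_label) != n:
                raise DimensionError(
                    "manual_label length does not match event count")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("values contain non-finite entries")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def raw(self) -> np.ndarray:
        """Intensities on the raw (untransformed) scale."""
        return self.values if self.raw_values is None else self.raw_values

    def subset(self, idx) -> "EventMatrix":
        idx = np.asarray(idx)
        return EventMatrix(
            values=self.values[idx],
            channels=list(self.channels),
            sample_id=self.sample_id[idx],
            event_index=self.event_index[idx],
            manual_label=None if self.manual_label is None
            else self.manual_label[idx],
            raw_values=None if self.raw_values is None
            else self.raw_values[idx],
            n_dropped=0,
        )

    def canonical_order(self) -> np.ndarray:
        """Row permutation sorting events by (sample_id, event_index)."""
        return np.lexsort((self.event_index, self.sample_id.astype(str)))

    def sorted_canonical(self) -> "EventMatrix":
        return self.subset(self.canonical_order())

    def samples(self) -> list[str]:
        """Sample identifiers in sorted order."""
        return sorted(set(self.sample_id.astype(str)))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.raw, columns=self.channels)
        df.insert(0, "event_index", self.event_index)
        df.insert(0, "sample_id", self.sample_id.astype(str))
        if self.manual_label is not None:
            df["manual_label"] = self.manual_label.astype(str)
        return df


@dataclass(frozen=True)
class TransformSpec:
    """How raw intensities map into clustering space.

    ``arcsinh`` applies ``x -> asinh(x / cofactor)`` — near-linear around
    zero and logarithmic for bright signals, the standard compression for
    fluorescence data.  ``per_channel_0_100`` then linearly maps each
    channel's observed range onto [0, 100] so that a unit-increment distance
    grid is meaningful regardless of instrument gain.
    """

    method: str = "arcsinh"
    cofactor: float = 150.0
    rescale: str = "per_channel_0_100"

    def __post_init__(self):
        if self.method not in ("none", "arcsinh"):
            raise ParameterError(f"unknown transform method {self.method!r}")
        if self.rescale not in ("none", "per_channel_0_100"):
            raise ParameterError(f"unknown rescale mode {self.rescale!r}")
        if not (np.isfinite(self.cofactor) and self.cofactor > 0):
            raise ParameterError("cofactor must be finite and positive")


def transform_channels(m: EventMatrix, spec: TransformSpec) -> EventMatrix:
    """Return a copy of ``m`` with values mapped into clustering space.

    Raw intensities are retained in ``raw_values`` so that MFI reporting
    stays on the original scale.  Each channel's ordering is preserved
    (both steps are monotone).
    """
    if m.n_events == 0:
        raise EmptyInputError("cannot transform an empty event matrix")
    x = m.raw.copy()
    if spec.method == "arcsinh":
        x = np.arcsinh(x / spec.cofactor)
    if spec.rescale == "per_channel_0_100":
        lo = x.min(axis=0)
        hi = x.max(axis=0)
        span = hi - lo
        keep = span > 0
        x[:, keep] = (x[:, keep] - lo[keep]) / span[keep] * 100.0
        x[:, ~keep] = 0.0
    return replace(m, values=x, raw_values=m.raw.copy(), n_dropped=0)


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def _read_label_file(path, n_events: int) -> np.ndarray:
    """Labels as one name per line, or two-column (event_index, label)."""
    path = Path(path)
    rows = [ln.rstrip("\n") for ln in path.read_text().splitlines()
            if ln.strip()]
    if rows and ("\t" in rows[0] or "," in rows[0]):
        sep = "\t" if "\t" in rows[0] else ","
        first = rows[0].split(sep)
        header = not first[0].strip().lstrip("-").isdigit()
        body = rows[1:] if header else rows
        if len(body) != n_events:
            raise DimensionError(
                f"label file has {len(body)} rows for {n_events} events")
        labels = np.empty(n_events, dtype=object)
        for ln in body:
            fields = ln.split(sep)
            try:
                i = int(fields[0])
            except ValueError as exc:
                raise FormatError(
                    f"label file row {ln!r}: bad event index") from exc
            if not 0 <= i < n_events:
                raise DimensionError(
                    f"label event_index {i} out of range 0..{n_events - 1}")
            labels[i] = fields[1].strip()
        if any(v is None for v in labels):
            raise FormatError("label file leaves some events unlabeled")
        return labels
    if len(rows) != n_events:
        raise DimensionError(
            f"label file has {len(rows)} rows for {n_events} events")
    return np.array([r.strip() for r in rows], dtype=object)


def _load_csv(path):
    try:
        with open(path) as fh:
            first = fh.readline()
        sep = "\t" if "\t" in first else ","
        df = pd.read_csv(path, sep=sep)
    except OSError:
        raise
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse delimited text: {exc}") from exc
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise EmptyInputError(f"{path}: no events in file")
    meta_cols = [c for c in ("sample_id", "event_index", "manual_label")
                 if c in df.columns]
    chan_cols = [c for c in df.columns if c not in meta_cols]
    for c in chan_cols:
        if not np.issubdtype(df[c].dtype, np.number):
            coerced = pd.to_numeric(df[c], errors="coerce")
            if coerced.isna().all():
                raise FormatError(
                    f"{path}: column {c!r} is not numeric "
                    f"(first value {df[c].iloc[0]!r})")
            df[c] = coerced
    values = df[chan_cols].to_numpy(dtype=np.float64)
    sample_id = (df["sample_id"].astype(str).to_numpy(dtype=object)
                 if "sample_id" in meta_cols
                 else np.full(len(df), Path(path).stem, dtype=object))
    event_index = (df["event_index"].to_numpy(dtype=np.int64)
                   if "event_index" in meta_cols else None)
    manual = (df["manual_label"].astype(str).to_numpy(dtype=object)
              if "manual_label" in meta_cols else None)
    return values, chan_cols, sample_id, event_index, manual


def load_event_matrix(path, format: str | None = None,
                      label_path=None) -> EventMatrix:
    """Load an event matrix from FCS or delimited text.

    Parameters
    ----------
    path
        Input file.  ``format`` is inferred from the suffix when not given
        (``.fcs`` vs anything else as delimited text).
    label_path
        Optional manual-gate label file whose row count must match the
        event count of the input (before non-finite filtering).

    Returns
    -------
    EventMatrix
        Channels in file order; events keep file order as ``event_index``
        (per sample); rows with non-finite values are dropped and counted
        in ``n_dropped``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "fcs" if path.suffix.lower() == ".fcs" else "csv"
    if format == "fcs":
        values, channels, _meta = read_fcs(path)
        sample_id = np.full(values.shape[0], path.stem, dtype=object)
        event_index = None
        manual = None
    elif format == "csv":
        values, channels, sample_id, event_index, manual = _load_csv(path)
    else:
        raise ParameterError(f"unknown format {format!r}")

    n_raw = values.shape[0]
    if label_path is not None:
        labels = _read_label_file(label_path, n_raw)
        manual = labels

    if event_index is None:
        event_index = np.empty(n_raw, dtype=np.int64)
        for s in np.unique(sample_id.astype(str)):
            mask = sample_id.astype(str) == s
            event_index[mask] = np.arange(int(mask.sum()))

    finite = np.isfinite(values).all(axis=1)
    n_dropped = int(n_raw - finite.sum())
    if n_dropped:
        logger.info("dropped %d events with non-finite values", n_dropped)
        values = values[finite]
        sample_id = sample_id[finite]
        event_index = event_index[finite]
        if manual is not None:
            manual = manual[finite]
    if values.shape[0] == 0:
        raise EmptyInputError(f"{path}: zero events after filtering")

    return EventMatrix(values=values, channels=channels, sample_id=sample_id,
                       event_index=event_index, manual_label=manual,
                       n_dropped=n_dropped)


def write_event_table(m: EventMatrix, path) -> None:
    """Write the canonical event table (sample_id, event_index, channels)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    m.to_frame().to_csv(path, sep=sep, index=False)


def write_fcs_matrix(m: EventMatrix, path) -> None:
    """Write raw intensities as a minimal FCS 3.1 file."""
    write_fcs(path, m.raw, m.channels)


__all__ = [
    "EventMatrix", "TransformSpec", "transform_channels",
    "load_event_matrix", "write_event_table", "write_fcs_matrix",
    "read_fcs", "write_fcs", "RESERVED_UNGATED",
]
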