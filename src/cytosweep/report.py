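"""Presentation artifacts: heatmaps and 2-D embeddings.

Figures are rendered with matplotlib (Agg backend); every figure writer
also exports the exact plotted table as delimited text, so the figures are
pure views — the numeric record lives in the tables.  Heatmaps display
per-channel min-max-scaled MFI while the exported tables carry the raw
values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .exceptions import ParameterError  # noqa: E402


def embed_2d(points, labels=None, perplexity: float = 30.0, seed: int = 0,
             max_events: int = 50000) -> np.ndarray:
    """t-SNE embedding of events into 2-D.

    Deterministic for a fixed seed.  Inputs larger than ``max_events`` are
    subsampled with a seeded uniform draw; the returned array has one row
    per *embedded* event and columns (row_index, x, y) so the subsample is
    traceable back to the input rows.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[0] < 10:
        raise ParameterError("embedding needs at least 10 points")
    rng = np.random.default_rng(seed)
    n = pts.shape[0]
    if n > max_events:
        rows = np.sort(rng.choice(n, max_events, replace=False))
    else:
        rows = np.arange(n)
    from sklearn.manifold import TSNE
    perp = min(perplexity, (len(rows) - 1) / 3.0)
    emb = TSNE(n_components=2, perplexity=perp, random_state=seed,
               init="pca").fit_transform(pts[rows])
    return np.column_stack([rows, emb])


def write_embedding(path, coords, sample_id, event_index, cluster_id,
                    population=None, sep="\t") -> pd.DataFrame:
    """Write embedding coordinates with identity columns for plotting."""
    rows = coords[:, 0].astype(int)
    df = pd.DataFrame({
        "sample_id": np.asarray(sample_id).astype(str)[rows],
        "event_index": np.asarray(event_index)[rows],
        "x": coords[:, 1],
        "y": coords[:, 2],
        "cluster_id": np.asarray(cluster_id)[rows],
    })
    if population is not None:
        df["population"] = np.asarray(population).astype(str)[rows]
    df.to_csv(path, sep=sep, index=False)
    return df


def _minmax_scale_columns(mat: pd.DataFrame) -> pd.DataFrame:
    lo, hi = mat.min(axis=0), mat.max(axis=0)
    span = (hi - lo).replace(0, 1.0)
    return (mat - lo) / span


def mfi_heatmap(mfi: pd.DataFrame, channels, fig_path=None, table_path=None):
    """Cluster x channel MFI heatmap (display min-max scaled per channel).

    ``mfi`` is the frame from :func:`cytosweep.annotate.cluster_mfi`; the
    exported table keeps raw MFI values, the figure shows each channel
    scaled to [0, 1] across clusters (the usual display convention).
    """
    body = mfi[mfi["cluster_id"] != 0].set_index("cluster_id")[list(channels)]
    if table_path is not None:
        body.to_csv(table_path)
    if fig_path is not None:
        disp = _minmax_scale_columns(body)
        fig, ax = plt.subplots(
            figsize=(1 + 0.4 * len(channels), 1 + 0.25 * len(body)))
        im = ax.imshow(disp.to_numpy(), aspect="auto", cmap="viridis",
                       vmin=0, vmax=1)
        ax.set_xticks(range(len(channels)), channels, rotation=90)
        ax.set_yticks(range(len(body)), body.index)
        ax.set_ylabel("cluster")
        fig.colorbar(im, ax=ax, label="scaled MFI")
        fig.tight_layout()
        fig.savefig(fig_path, dpi=150)
        plt.close(fig)
    return body


def frequency_heatmap(fractions: pd.DataFrame, fig_path=None,
                      table_path=None, log_floor: float = 1e-4):
    """Cluster/population x sample frequency heatmap (log10 display)."""
    if table_path is not None:
        fractions.to_csv(table_path)
    if fig_path is not None:
        disp = np.log10(np.maximum(fractions.to_numpy(dtype=float),
                                   log_floor))
        fig, ax = plt.subplots(
            figsize=(1 + 0.35 * fractions.shape[1],
                     1 + 0.25 * fractions.shape[0]))
        im = ax.imshow(disp, aspect="auto", cmap="magma")
        ax.set_xticks(range(fractions.shape[1]), fractions.columns,
                      rotation=90)
        ax.set_yticks(range(fractions.shape[0]),
                      [str(i) for i in fractions.index])
        fig.colorbar(im, ax=ax, label="log10 fraction of sample")
        fig.tight_layout()
        fig.savefig(fig_path, dpi=150)
        plt.close(fig)
    return fractions


def embedding_figure(df: pd.DataFrame, fig_path, color: str = "cluster_id",
                     max_legend: int = 25):
    """Scatter of an embedding table colored by cluster or population."""
    groups = df.groupby(color, sort=True)
    fig, ax = plt.subplots(figsize=(7, 6))
    cmap = plt.get_cmap("tab20")
    for i, (name, g) in enumerate(groups):
        ax.scatter(g["x"], g["y"], s=2, color=cmap(i % 20),
                   label=str(name) if i < max_legend else None,
                   rasterized=True)
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    if len(groups) <= max_legend:
        ax.legend(markerscale=4, fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(fig_path, dpi=150)
    plt.close(fig)


__all__ = ["embed_2d", "write_embedding", "mfi_heatmap",
           "frequency_heatmap", "embedding_figure"]
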