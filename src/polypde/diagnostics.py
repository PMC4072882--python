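"""Library-level QC: Euclidean distances, 2-D embedding, MA and dispersion data.

Distances are computed between per-library vectors of log2(normalized
count + 1) — a simple, monotone variance-tamer. The 2-D embedding is
classical (Torgerson) multidimensional scaling with a fixed sign
convention so runs are comparable.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd

from .de_core import DispersionFit, normalized_counts


def library_distances(
    counts: pd.DataFrame,
    factors: pd.Series,
    exclude: Iterable[str] = (),
) -> pd.DataFrame:
    """Symmetric Euclidean distance matrix between libraries.

    ``exclude`` drops transcripts (e.g. screen-significant heterogametic
    ones) before the distance computation.
    """
    drop = set(exclude)
    kept = counts.loc[[t for t in counts.index if t not in drop]]
    if kept.empty:
        raise ValueError("transcript exclusion removed every transcript")
    x = np.log2(normalized_counts(kept, factors).to_numpy() + 1.0)
    # pairwise Euclidean over library columns
    gram = x.T @ x
    sq = np.diag(gram)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * gram, 0.0)
    d = np.sqrt(d2)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return pd.DataFrame(d, index=counts.columns, columns=counts.columns)


def mds_2d(distances: pd.DataFrame) -> pd.DataFrame:
    """Classical (Torgerson) scaling of a distance matrix to 2-D.

    Double-centre -d^2/2, take the top two eigenpairs (descending
    eigenvalue), and scale eigenvectors by sqrt(eigenvalue). The sign of
    each axis is fixed by making its first non-zero loading positive,
    walking the libraries in label order so the convention is invariant
    to row permutations. If fewer than two positive eigenvalues exist the
    second coordinate is zero and a warning is emitted.
    """
    d = distances.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be square and symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    coords = np.zeros((n, 2))
    n_pos = int((eigval[:2] > 1e-12).sum())
    if n_pos < 2:
        warnings.warn("fewer than 2 positive eigenvalues; returning a 1-D embedding")
    label_order = np.argsort([str(label) for label in distances.index])
    for axis in range(min(2, n_pos) if n_pos else 1):
        if eigval[axis] <= 0:
            continue
        v = eigvec[:, axis] * np.sqrt(eigval[axis])
        nz = [i for i in label_order if abs(v[i]) > 1e-12]
        if nz and v[nz[0]] < 0:
            v = -v
        coords[:, axis] = v
    return pd.DataFrame(coords, index=distances.index, columns=["x", "y"])


def ma_data(de_table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """MA-plot data: mean normalized count, log2FC and significance flag."""
    tested = de_table["tested"].astype(bool)
    out = de_table.loc[tested, ["base_mean", "log2_fold_change"]].copy()
    out["significant"] = (de_table.loc[tested, "p_adj"] < alpha).fillna(False)
    return out


def dispersion_mean_data(
    fit: DispersionFit, grid_points: int = 50
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dispersion-vs-mean export plus the trend curve on a log-spaced grid."""
    table = fit.table
    per_transcript = table.loc[
        table["tested"], ["base_mean", "raw_alpha", "fitted_alpha", "final_alpha"]
    ].copy()
    a0, a1 = fit.trend
    q = per_transcript["base_mean"]
    lo = max(float(q.min()), 1e-3)
    hi = max(float(q.max()), lo * 10)
    grid = np.logspace(np.log10(lo), np.log10(hi), grid_points)
    trend = pd.DataFrame({"base_mean": grid, "trend_alpha": a0 + a1 / grid})
    return per_transcript, trend


def within_between_ratio(distances: pd.DataFrame, design: pd.DataFrame) -> float:
    """Mean within-gonozooid distance over mean gonozooid-to-other distance.

    Drops toward the polyp-clustered regime when heterogametic transcripts
    are removed.
    """
    gono = design.loc[design["polyp"] == "gonozooid", "library_id"].tolist()
    other = design.loc[design["polyp"] != "gonozooid", "library_id"].tolist()
    if len(gono) < 2 or not other:
        raise ValueError("need >= 2 gonozooid and >= 1 other library")
    within = [distances.loc[a, b] for i, a in enumerate(gono) for b in gono[i + 1:]]
    between = [distances.loc[a, b] for a in gono for b in other]
    return float(np.mean(within) / np.mean(between))


def plot_diagnostics(distances, embedding, ma, dispersion_points, trend, out_path):
    """Optional convenience figure (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(10, 9))
    im = axes[0, 0].imshow(distances.to_numpy(), cmap="viridis")
    axes[0, 0].set_xticks(range(len(distances)), distances.columns, rotation=90, fontsize=6)
    axes[0, 0].set_yticks(range(len(distances)), distances.index, fontsize=6)
    axes[0, 0].set_title("library distances")
    fig.colorbar(im, ax=axes[0, 0])

    axes[0, 1].scatter(embedding["x"], embedding["y"])
    for lib, row in embedding.iterrows():
        axes[0, 1].annotate(lib, (row["x"], row["y"]), fontsize=6)
    axes[0, 1].set_title("2-D embedding")

    colors = np.where(ma["significant"], "red", "grey")
    axes[1, 0].scatter(ma["base_mean"], ma["log2_fold_change"], s=4, c=colors)
    axes[1, 0].set_xscale("log")
    axes[1, 0].set_title("MA")

    axes[1, 1].scatter(
        dispersion_points["base_mean"], dispersion_points["raw_alpha"], s=3, c="grey"
    )
    axes[1, 1].plot(trend["base_mean"], trend["trend_alpha"], c="red")
    axes[1, 1].set_xscale("log")
    axes[1, 1].set_yscale("log")
    axes[1, 1].set_title("dispersion vs mean")

    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
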