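"""Cross-experiment binding-profile PCA and heatmap matrices.

Experiments (not sites) are the PCA observations: the input count
matrix has sites as rows and experiment replicates as columns, is
log2(c+1)-transformed and column(site)-centered, and each component's
sign is fixed by making its largest-magnitude loading positive.
Heatmap rows are events ordered by binding significance; the color
ceiling is the count of the bin at the 85th percentile of all bins
ordered by count, with a fixed floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Genome, TagLibrary
from .events import merge_summits, rank_top


def union_top_sites(events_by_tf: dict[str, pd.DataFrame], n: int = 10_000,
                    merge_radius: int = 50) -> pd.DataFrame:
    """Union of each TF's top-n summits, merged within ``merge_radius``."""
    frames = []
    for tf, ev in events_by_tf.items():
        top = rank_top(ev, n)[["chrom", "point"]].copy()
        top["tf"] = tf
        frames.append(top)
    allpts = pd.concat(frames, ignore_index=True)
    merged = merge_summits(allpts, merge_radius)
    return merged[["chrom", "point"]]


@dataclass
class PCAResult:
    scores: pd.DataFrame        # experiments x components
    loadings: np.ndarray        # sites x components
    variance_fraction: np.ndarray


def pca_profiles(count_matrix: pd.DataFrame, log_transform: bool = True,
                 center: bool = True) -> PCAResult:
    """PCA of experiment binding profiles over a shared site list.

    ``count_matrix``: rows are sites, columns are experiments/replicates.
    """
    if count_matrix.shape[1] < 2 or count_matrix.shape[0] < 2:
        raise ValueError("need >= 2 experiments and >= 2 sites")
    X = count_matrix.to_numpy(dtype=float).T  # experiments as observations
    if log_transform:
        X = np.log2(X + 1.0)
    if center:
        X = X - X.mean(axis=0, keepdims=True)
    if not np.any(X):
        raise ValueError("count matrix has no variance")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    var = S ** 2
    if var.sum() == 0:
        raise ValueError("count matrix has no variance")
    frac = var / var.sum()
    scores = U * S
    loadings = Vt.T
    # fix signs: largest-magnitude loading of each component positive
    for j in range(loadings.shape[1]):
        imax = np.argmax(np.abs(loadings[:, j]))
        if loadings[imax, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comp_names = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=count_matrix.columns, columns=comp_names),
        loadings=loadings, variance_fraction=frac)


def profile_count_matrix(sites: pd.DataFrame,
                         libs_by_experiment: dict[str, TagLibrary],
                         window: int = 200) -> pd.DataFrame:
    """Window tag counts at each site for each experiment replicate."""
    from .events import _counts_at_points
    half = window // 2
    data = {name: _counts_at_points(lib, sites, half)
            for name, lib in libs_by_experiment.items()}
    return pd.DataFrame(data, index=sites.index)


@dataclass
class HeatmapMatrix:
    matrix: np.ndarray          # events x bins
    vmin: float
    vmax: float
    order: np.ndarray           # row order applied (indices into input events)
    bin_width: int


def _percentile_bin_value(flat: np.ndarray, percentile: float) -> float:
    """Value of the bin sitting at the given percentile when all bins are
    ordered by count (lower order statistic)."""
    s = np.sort(flat)
    if len(s) == 0:
        return 0.0
    idx = min(int(np.ceil(percentile / 100.0 * len(s))) - 1, len(s) - 1)
    return float(s[max(idx, 0)])


def heatmap_matrix(events: pd.DataFrame, lib: TagLibrary, genome: Genome,
                   window: int = 1_000, bin: int = 100, extend: int = 100,
                   floor: float = 5.0, percentile: float = 85.0) -> HeatmapMatrix:
    """Extended-read bin counts around events, ordered by peak strength.

    Reads are extended ``extend`` bp 3'-ward; a bin counts the reads
    whose extension overlaps it.  Rows are re-sorted internally by
    (q_binding asc, signal desc) so input order does not matter.
    """
    order_df = events.reset_index(drop=True)
    sort_cols = [c for c in ("q_binding", "signal") if c in order_df.columns]
    if sort_cols:
        asc = [c == "q_binding" for c in sort_cols]
        order = order_df.sort_values(sort_cols, ascending=asc,
                                     kind="stable").index.to_numpy()
    else:
        order = np.arange(len(order_df))
    n_bins = window // bin
    mat = np.zeros((len(order_df), n_bins), dtype=np.int64)

    ext = {}
    for chrom, ct in lib.tags.items():
        if ct.n == 0:
            continue
        starts = np.where(ct.strands, ct.positions - extend + 1, ct.positions)
        ends = np.where(ct.strands, ct.positions + 1, ct.positions + extend)
        clen = genome.lengths[chrom]
        starts = np.clip(starts, 0, clen)
        ends = np.clip(ends, 0, clen)
        ext[chrom] = (np.sort(starts), np.sort(ends))

    for i, (_, ev) in enumerate(order_df.iterrows()):
        if ev.chrom not in ext:
            continue
        starts_sorted, ends_sorted = ext[ev.chrom]
        left = int(ev.point) - window // 2
        edges = left + np.arange(n_bins + 1) * bin
        # reads overlapping [b0, b1): start < b1 and end > b0
        n_start_before = np.searchsorted(starts_sorted, edges[1:], side="left")
        n_end_before = np.searchsorted(ends_sorted, edges[:-1], side="right")
        mat[i] = n_start_before - n_end_before
    vmax = max(floor, _percentile_bin_value(mat.ravel(), percentile))
    return HeatmapMatrix(matrix=mat[order], vmin=floor, vmax=vmax,
                         order=order, bin_width=bin)
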