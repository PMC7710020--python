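"""Accessible-domain calling and accessibility quantification at site sets.

Domains are contiguous runs of bins whose pooled ATAC tag count exceeds
a Poisson upper tail of the genome-average rate, merged across small
gaps and length-filtered.  Site-level accessibility is measured as tags
per million in a window around the site point, normalized per replicate
before averaging; composite profiles follow the metagene convention
(tags per million per 1000 sites at each offset).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import Genome, TagLibrary, window_counts


@dataclass
class QuartileSummary:
    min: float
    q1: float
    median: float
    q3: float
    max: float
    n: int

    @classmethod
    def from_values(cls, values: np.ndarray) -> "QuartileSummary":
        v = np.asarray(values, dtype=float)
        # linear interpolation between order statistics (numpy default)
        q = np.quantile(v, [0.0, 0.25, 0.5, 0.75, 1.0])
        return cls(*[float(x) for x in q], n=len(v))


def call_domains(atac_libs: list[TagLibrary], genome: Genome, bin: int = 50,
                 p_thresh: float = 1e-3, merge_gap: int = 200,
                 min_len: int = 200) -> pd.DataFrame:
    """Call accessible domains from pooled ATAC 5'-tag bin counts.

    Returns a sorted, non-overlapping BED-like DataFrame (chrom, start,
    end, mean_density) where mean_density is tags per million per bp.
    """
    total = sum(lib.total for lib in atac_libs)
    if total == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "mean_density"])
    rate = total / genome.total_length * bin  # expected pooled tags per bin
    rows = []
    for chrom in genome.chrom_names:
        L = genome.lengths[chrom]
        n_bins = -(-L // bin)
        counts = np.zeros(n_bins, dtype=np.int64)
        for lib in atac_libs:
            pos = lib.chrom_positions(chrom)
            if len(pos):
                counts += np.bincount(pos // bin, minlength=n_bins)
        thresh = stats.poisson.isf(p_thresh, rate)
        sig = counts > thresh
        idx = np.flatnonzero(sig)
        if len(idx) == 0:
            continue
        gap_bins = merge_gap // bin
        breaks = np.flatnonzero(np.diff(idx) > gap_bins + 1)
        for grp in np.split(idx, breaks + 1):
            start = int(grp[0]) * bin
            end = min(int(grp[-1] + 1) * bin, L)
            if end - start < min_len:
                continue
            dom_tags = int(counts[grp[0]: grp[-1] + 1].sum())
            rows.append({"chrom": chrom, "start": start, "end": end,
                         "mean_density": dom_tags * 1e6 / total / (end - start)})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "mean_density"])


def site_density(sites: pd.DataFrame, atac_libs: list[TagLibrary],
                 window: int = 2_000) -> tuple[pd.Series, QuartileSummary]:
    """Tags per million per site in +-window/2 around each site point,
    normalized per replicate then averaged over replicates."""
    if window < 1:
        raise ValueError("window must be >= 1")
    half = window // 2
    dens = np.zeros(len(sites), dtype=float)
    for lib in atac_libs:
        scale = 1e6 / lib.total if lib.total else 0.0
        vals = np.zeros(len(sites), dtype=float)
        chroms = sites["chrom"].to_numpy()
        points = sites["point"].to_numpy()
        for chrom in pd.unique(chroms):
            mask = chroms == chrom
            pos = lib.chrom_positions(chrom)
            pts = points[mask]
            vals[mask] = window_counts(pos, pts - half, pts + half)
        dens += vals * scale
    dens /= max(len(atac_libs), 1)
    series = pd.Series(dens, index=sites.index, name="density_tpm")
    return series, QuartileSummary.from_values(dens)


def fraction_in_domains(sites: pd.DataFrame, domains: pd.DataFrame,
                        semantics: str = "point") -> float:
    """Fraction of site points falling inside any domain interval."""
    if semantics != "point":
        raise ValueError("only point semantics are implemented")
    if len(sites) == 0:
        return 0.0
    if len(domains) == 0:
        return 0.0
    inside = 0
    for chrom, sub in sites.groupby("chrom"):
        dom = domains[domains.chrom == chrom].sort_values("start")
        if len(dom) == 0:
            continue
        starts = dom["start"].to_numpy()
        ends = dom["end"].to_numpy()
        pts = sub["point"].to_numpy()
        idx = np.searchsorted(starts, pts, side="right") - 1
        ok = (idx >= 0) & (pts < ends[np.clip(idx, 0, None)])
        inside += int(ok.sum())
    return inside / len(sites)


def composite_profile(sites: pd.DataFrame, atac_libs: list[TagLibrary],
                      half_window: int = 1_000, extend: int = 100) -> np.ndarray:
    """Replicate-averaged metagene profile around site points.

    Per replicate, reads extended ``extend`` bp 3'-ward are summed over
    sites at each offset in [-half_window, half_window), scaled by
    1e6/total and 1000/n_sites, then averaged over replicates.  Returns
    a vector of length 2*half_window.
    """
    if len(sites) == 0:
        raise ValueError("need at least one site")
    width = 2 * half_window
    profile = np.zeros(width, dtype=float)
    chroms = sites["chrom"].to_numpy()
    points = sites["point"].to_numpy()
    for lib in atac_libs:
        cover = np.zeros(width + 1, dtype=np.int64)
        for chrom in pd.unique(chroms):
            ct = lib.tags.get(chrom)
            if ct is None or ct.n == 0:
                continue
            pos, minus = ct.positions, ct.strands
            ext_start = np.where(minus, pos - extend + 1, pos)
            ext_end = np.where(minus, pos + 1, pos + extend)
            for point in points[chroms == chrom]:
                lo = np.searchsorted(pos, point - half_window - extend)
                hi = np.searchsorted(pos, point + half_window + extend)
                if hi <= lo:
                    continue
                a = np.clip(ext_start[lo:hi] - (point - half_window), 0, width)
                b = np.clip(ext_end[lo:hi] - (point - half_window), 0, width)
                keep = b > a
                np.add.at(cover, a[keep], 1)
                np.subtract.at(cover, b[keep], 1)
        coverage = np.cumsum(cover[:-1])
        scale = (1e6 / lib.total if lib.total else 0.0) * (1_000 / len(sites))
        profile += coverage * scale
    return profile / max(len(atac_libs), 1)


def accessibility_change(sites: pd.DataFrame, libs_before: list[TagLibrary],
                         libs_after: list[TagLibrary], window: int = 2_000
                         ) -> tuple[pd.Series, pd.DataFrame | None]:
    """Per-site density change (after - before, tags per million) and,
    when sites carry a ``category`` column, per-category mean/sem."""
    before, _ = site_density(sites, libs_before, window)
    after, _ = site_density(sites, libs_after, window)
    delta = (after - before).rename("delta_tpm")
    summary = None
    if "category" in sites.columns:
        df = pd.DataFrame({"category": sites["category"].to_numpy(),
                           "delta": delta.to_numpy()})
        grp = df.groupby("category")["delta"]
        summary = pd.DataFrame({
            "mean": grp.mean(),
            "sem": grp.sem(),
            "n": grp.size()}).reset_index()
    return delta, summary
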