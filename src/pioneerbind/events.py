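"""Point-source binding-event calling and differential-binding categories.

The caller scores sliding windows of pooled replicate 5'-tag counts
against an input-control expectation (local scaled control count or the
global genome-wide rate, whichever is larger) with a Poisson upper-tail
test, applies Benjamini-Hochberg across all tested windows, merges
significant windows and places a summit at the maximum of the smoothed
tag density.

Differential binding between TFs uses the exact negative-binomial
conditional test with a method-of-moments common dispersion; sites are
the union of per-TF event summits merged within a small radius, and the
multi-way category labels follow the shared / TF1>TF2,TF3 / TF1,TF2>TF3
vocabulary with a minimum retained-category size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import Genome, TagLibrary, window_counts
from .genesets import bh_adjust

UNCLASSIFIED = "unclassified/minor"


@dataclass
class TestConfig:
    """Thresholds for binding and differential significance."""

    q_bind: float = 1e-3        # binding-event q-value cutoff
    q_diff: float = 1e-2        # differential-binding q-value cutoff
    window: int = 200           # caller window / differential count window (bp)
    step: int = 50              # caller window step (bp)
    control_window: int = 5_000  # local control estimation window (bp)
    min_category: int = 500     # minimum retained category size
    top_n: int = 10_000         # per-TF top-site restriction
    merge_radius: int = 100     # cross-TF summit merge radius (bp)
    summit_smooth: int = 41     # boxcar width for summit density (bp)
    default_dispersion: float = 0.05  # fallback phi with no replication

    def __post_init__(self):
        if not (0 < self.q_bind < 1 and 0 < self.q_diff < 1):
            raise ValueError("q thresholds must be in (0, 1)")


# --------------------------------------------------------------------------
# event calling


def _pooled_positions(libs: list[TagLibrary], chrom: str) -> np.ndarray:
    parts = [lib.chrom_positions(chrom) for lib in libs]
    pos = np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)
    pos.sort()
    return pos


def call_events(signal_libs: list[TagLibrary], control_lib: TagLibrary | None,
                genome: Genome, config: TestConfig | None = None) -> pd.DataFrame:
    """Call point-source binding events versus an input control.

    Returns a DataFrame (chrom, point, signal, p_binding, q_binding and
    per-replicate window counts cnt0..cntN) of events with q < q_bind,
    sorted by (q asc, signal desc, coordinate asc).  Window counts are
    taken in +-window/2 around the summit.
    """
    config = config or TestConfig()
    if not signal_libs:
        raise ValueError("need at least one signal replicate")
    sig_total = sum(lib.total for lib in signal_libs)
    if sig_total == 0:
        return _empty_events(len(signal_libs))
    ctrl_total = control_lib.total if control_lib is not None else 0
    W, step = config.window, config.step
    global_rate = sig_total / genome.total_length  # pooled tags per bp

    chrom_windows = {}
    all_p = []
    for chrom in genome.chrom_names:
        L = genome.lengths[chrom]
        starts = np.arange(0, max(L - W, 0) + 1, step, dtype=np.int64)
        pooled = _pooled_positions(signal_libs, chrom)
        k = window_counts(pooled, starts, starts + W)
        expected = np.full(len(starts), global_rate * W)
        if control_lib is not None and ctrl_total > 0:
            cpos = control_lib.chrom_positions(chrom)
            half = config.control_window // 2
            centers = starts + W // 2
            local = window_counts(cpos, centers - half, centers + half)
            scaled = local * (sig_total / ctrl_total) * (W / config.control_window)
            expected = np.maximum(expected, scaled)
        p = stats.poisson.sf(k - 1, expected)
        chrom_windows[chrom] = (starts, k, p, pooled)
        all_p.append(p)

    pvec = np.concatenate(all_p)
    qvec = bh_adjust(pvec)
    offset = 0
    events = []
    for chrom in genome.chrom_names:
        starts, k, p, pooled = chrom_windows[chrom]
        q = qvec[offset: offset + len(starts)]
        offset += len(starts)
        sig = np.flatnonzero((q < config.q_bind) & (k > 0))
        if len(sig) == 0:
            continue
        # merge overlapping/adjacent significant windows into regions
        breaks = np.flatnonzero(np.diff(starts[sig]) > W)
        groups = np.split(sig, breaks + 1)
        for grp in groups:
            rs, re = starts[grp[0]], starts[grp[-1]] + W
            summit = _summit(pooled, rs, re, config.summit_smooth)
            best = grp[np.argmin(p[grp])]
            events.append({"chrom": chrom, "point": summit,
                           "p_binding": float(p[best]), "q_binding": float(q[best])})
    if not events:
        return _empty_events(len(signal_libs))
    df = pd.DataFrame(events)
    half = W // 2
    for i, lib in enumerate(signal_libs):
        df[f"cnt{i}"] = _counts_at_points(lib, df, half)
    cnt_cols = [f"cnt{i}" for i in range(len(signal_libs))]
    df["signal"] = df[cnt_cols].sum(axis=1) * 1e6 / sig_total
    df = df.sort_values(["q_binding", "signal", "chrom", "point"],
                        ascending=[True, False, True, True], kind="stable")
    return df.reset_index(drop=True)


def _empty_events(n_reps: int) -> pd.DataFrame:
    cols = ["chrom", "point", "p_binding", "q_binding"] + \
        [f"cnt{i}" for i in range(n_reps)] + ["signal"]
    return pd.DataFrame(columns=cols)


def _summit(pooled: np.ndarray, start: int, end: int, smooth: int) -> int:
    """Position of maximum boxcar-smoothed tag density (leftmost on ties)."""
    lo = np.searchsorted(pooled, start - smooth)
    hi = np.searchsorted(pooled, end + smooth)
    local = pooled[lo:hi]
    length = end - start
    density = np.zeros(length, dtype=np.int64)
    if len(local):
        half = smooth // 2
        a = np.clip(local - half - start, 0, length)
        b = np.clip(local + half + 1 - start, 0, length)
        np.add.at(density, a[a < length], 1)
        np.subtract.at(density, b[b < length], 1)
        density = np.cumsum(density)
    return int(start + np.argmax(density))


def _counts_at_points(lib: TagLibrary, sites: pd.DataFrame, half: int) -> np.ndarray:
    out = np.zeros(len(sites), dtype=np.int64)
    points = sites["point"].to_numpy()
    chroms = sites["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        mask = chroms == chrom
        pos = lib.chrom_positions(chrom)
        pts = points[mask]
        out[mask] = window_counts(pos, pts - half, pts + half)
    return out


def rank_top(events: pd.DataFrame, n: int) -> pd.DataFrame:
    """Best n events by (q asc, signal desc, coordinate asc)."""
    df = events.sort_values(["q_binding", "signal", "chrom", "point"],
                            ascending=[True, False, True, True], kind="stable")
    return df.head(n).reset_index(drop=True)


# --------------------------------------------------------------------------
# dispersion and the exact NB test


def estimate_dispersion(counts: np.ndarray, lib_sizes: np.ndarray,
                        groups: np.ndarray | None = None,
                        default: float = 0.05) -> float:
    """Method-of-moments common dispersion on library-size-normalized counts.

    For each site and replicate group, the excess of the sample variance
    over the mean contributes to a pooled ratio estimator
    ``phi = sum(v - m) / sum(m^2)``, floored at 0.  With no replication
    anywhere the configured default is returned.
    """
    counts = np.asarray(counts, dtype=float)
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    if groups is None:
        groups = np.zeros(counts.shape[1], dtype=int)
    groups = np.asarray(groups)
    ref = np.exp(np.mean(np.log(lib_sizes)))
    norm = counts * (ref / lib_sizes)[None, :]
    num = 0.0
    den = 0.0
    replicated = False
    for g in np.unique(groups):
        sub = norm[:, groups == g]
        if sub.shape[1] < 2:
            continue
        replicated = True
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        num += float(np.sum(v - m))
        den += float(np.sum(m ** 2))
    if not replicated or den == 0:
        return default
    return max(num / den, 0.0)


def _nb_logpmf(k: np.ndarray, mean: float, phi: float) -> np.ndarray:
    if mean <= 0:
        out = np.full(len(k), -np.inf)
        out[k == 0] = 0.0
        return out
    if phi <= 0:
        return stats.poisson.logpmf(k, mean)
    r = 1.0 / phi
    p = r / (r + mean)
    return stats.nbinom.logpmf(k, r, p)


def nb_exact_test(counts_a, counts_b, lib_sizes_a, lib_sizes_b,
                  phi: float, method: str = "doubletail") -> float:
    """Two-sided exact NB conditional test of equal normalized means.

    Pooled counts are rescaled to a common library size, and the
    conditional distribution of condition A's pooled count given the
    pooled total is enumerated with per-condition dispersions phi/n
    (pooling n replicates divides the dispersion).  ``doubletail``
    doubles the smaller tail (capped at 1); ``minlik`` sums the
    probabilities of outcomes no more likely than the observed one.
    """
    counts_a = np.atleast_1d(np.asarray(counts_a, dtype=float))
    counts_b = np.atleast_1d(np.asarray(counts_b, dtype=float))
    sizes_a = np.atleast_1d(np.asarray(lib_sizes_a, dtype=float))
    sizes_b = np.atleast_1d(np.asarray(lib_sizes_b, dtype=float))
    if np.any(counts_a < 0) or np.any(counts_b < 0):
        raise ValueError("counts must be >= 0")
    if phi < 0:
        raise ValueError("phi must be >= 0")
    na, nb = len(counts_a), len(counts_b)
    ref = np.exp(np.mean(np.log(np.concatenate([sizes_a, sizes_b]))))
    ya = int(round(float(np.sum(counts_a * ref / sizes_a))))
    yb = int(round(float(np.sum(counts_b * ref / sizes_b))))
    t = ya + yb
    if t == 0:
        return 1.0
    k = np.arange(t + 1)
    mu_a = t * na / (na + nb)
    mu_b = t * nb / (na + nb)
    logw = _nb_logpmf(k, mu_a, phi / na) + _nb_logpmf(t - k, mu_b, phi / nb)
    logw -= logw.max()
    w = np.exp(logw)
    pmf = w / w.sum()
    if method == "doubletail":
        lower = float(pmf[: ya + 1].sum())
        upper = float(pmf[ya:].sum())
        return min(1.0, 2.0 * min(lower, upper))
    if method == "minlik":
        return float(pmf[pmf <= pmf[ya] * (1 + 1e-12)].sum())
    raise ValueError(f"unknown method {method!r}")


# --------------------------------------------------------------------------
# site matching and category assignment


def merge_summits(points_df: pd.DataFrame, radius: int) -> pd.DataFrame:
    """Single-linkage merge of summits within ``radius`` bp into sites.

    Input needs (chrom, point) plus arbitrary extra columns; output has
    one row per merged site with ``point`` the midpoint of the cluster
    extremes and ``members`` the list of input row indices.
    """
    rows = []
    df = points_df.reset_index(drop=True)
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values("point", kind="stable")
        pts = sub["point"].to_numpy()
        idx = sub.index.to_numpy()
        if len(pts) == 0:
            continue
        breaks = np.flatnonzero(np.diff(pts) > radius)
        for grp in np.split(np.arange(len(pts)), breaks + 1):
            rows.append({"chrom": chrom,
                         "point": int((pts[grp[0]] + pts[grp[-1]]) // 2),
                         "members": idx[grp].tolist()})
    return pd.DataFrame(rows)


@dataclass
class CategorizedSites:
    """Classified site union plus per-pair differential statistics."""

    sites: pd.DataFrame               # chrom, point, sig_<TF>, label, retained
    pair_stats: pd.DataFrame          # site, tf1, tf2, p_diff, q_diff, logfc columns
    counts: dict[str, np.ndarray] = field(default_factory=dict)
    dispersion: float = 0.0

    def category_counts(self, retained_only: bool = True) -> pd.Series:
        df = self.sites
        if retained_only:
            df = df[df.retained]
        return df["label"].value_counts()


def _site_union(events_by_tf: dict[str, pd.DataFrame], radius: int) -> pd.DataFrame:
    frames = []
    for tf, ev in events_by_tf.items():
        sub = ev[["chrom", "point", "q_binding"]].copy()
        sub["tf"] = tf
        frames.append(sub)
    allpts = pd.concat(frames, ignore_index=True)
    merged = merge_summits(allpts, radius)
    for tf in events_by_tf:
        merged[f"sig_{tf}"] = [
            any(allpts.loc[m, "tf"] == tf for m in members)
            for members in merged["members"]]
    return merged.drop(columns="members")


def _norm_counts(counts: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    ref = np.exp(np.mean(np.log(sizes)))
    return counts * (ref / sizes)[None, :]


def classify(events_by_tf: dict[str, pd.DataFrame],
             libs_by_tf: dict[str, list[TagLibrary]],
             input_lib: TagLibrary | None,
             config: TestConfig | None = None,
             phi: float | None = None) -> CategorizedSites:
    """Assign pairwise or multi-way differential-binding category labels.

    Works for two or three TFs.  Every site in the merged union gets
    exactly one label from the closed vocabulary (or "unclassified/minor");
    categories smaller than ``min_category`` are flagged not retained.
    """
    config = config or TestConfig()
    tf_names = list(events_by_tf)
    if len(tf_names) not in (2, 3):
        raise ValueError("classification supports 2 or 3 TFs")
    sites = _site_union(events_by_tf, config.merge_radius)
    half = config.window // 2

    counts = {}
    sizes = {}
    for tf in tf_names:
        libs = libs_by_tf[tf]
        mat = np.stack([_counts_at_points(lib, sites, half) for lib in libs], axis=1)
        counts[tf] = mat
        sizes[tf] = np.array([lib.total for lib in libs], dtype=float)
    if input_lib is not None:
        input_counts = _counts_at_points(input_lib, sites, half)
        input_size = float(input_lib.total)
    else:
        input_counts = np.zeros(len(sites))
        input_size = 1.0

    if phi is None:
        all_counts = np.concatenate([counts[tf] for tf in tf_names], axis=1)
        all_sizes = np.concatenate([sizes[tf] for tf in tf_names])
        groups = np.concatenate([
            np.full(counts[tf].shape[1], i) for i, tf in enumerate(tf_names)])
        phi = estimate_dispersion(all_counts, all_sizes, groups,
                                  default=config.default_dispersion)

    # logFC vs input on per-million normalized means with pseudocount 1
    logfc = {}
    input_cpm = input_counts * 1e6 / max(input_size, 1.0)
    for tf in tf_names:
        cpm = (counts[tf] / sizes[tf][None, :] * 1e6).mean(axis=1)
        logfc[tf] = np.log2(cpm + 1.0) - np.log2(input_cpm + 1.0)

    # pairwise exact tests; BH family per TF pair over tested sites
    pair_rows = []
    pdiff = {}
    qdiff = {}
    for i, a in enumerate(tf_names):
        for b in tf_names[i + 1:]:
            tested = np.flatnonzero(sites[f"sig_{a}"] | sites[f"sig_{b}"])
            pvals = np.array([
                nb_exact_test(counts[a][s], counts[b][s], sizes[a], sizes[b], phi)
                for s in tested])
            qvals = bh_adjust(pvals) if len(pvals) else pvals
            p_full = np.full(len(sites), np.nan)
            q_full = np.full(len(sites), np.nan)
            p_full[tested] = pvals
            q_full[tested] = qvals
            pdiff[(a, b)] = p_full
            qdiff[(a, b)] = q_full
            for s, p, q in zip(tested, pvals, qvals):
                pair_rows.append({"site": int(s), "tf1": a, "tf2": b,
                                  "p_diff": p, "q_diff": q,
                                  "logfc_1": logfc[a][s], "logfc_2": logfc[b][s]})

    def is_diff(a, b, s):
        key = (a, b) if (a, b) in qdiff else (b, a)
        q = qdiff[key][s]
        return bool(np.isfinite(q) and q < config.q_diff)

    def greater(a, b, s):
        return is_diff(a, b, s) and logfc[a][s] > logfc[b][s]

    labels = []
    for s in range(len(sites)):
        sig = {tf: bool(sites.at[s, f"sig_{tf}"]) for tf in tf_names}
        label = UNCLASSIFIED
        if len(tf_names) == 2:
            a, b = tf_names
            if sig[a] and sig[b] and not is_diff(a, b, s):
                label = f"{a}={b}"
            elif sig[a] and greater(a, b, s):
                label = f"{a}>{b}"
            elif sig[b] and greater(b, a, s):
                label = f"{b}>{a}"
        else:
            a, b, c = tf_names
            no_pair_diff = not any(is_diff(x, y, s)
                                   for x, y in ((a, b), (a, c), (b, c)))
            if all(sig.values()) and no_pair_diff:
                label = f"{a}={b}={c}"
            else:
                for x, y, z in ((a, b, c), (b, a, c), (c, a, b)):
                    if sig[x] and greater(x, y, s) and greater(x, z, s):
                        label = f"{x}>{y},{z}"
                        break
                else:
                    for x, y, z in ((a, b, c), (a, c, b), (b, c, a)):
                        if (sig[x] and sig[y] and not is_diff(x, y, s)
                                and greater(x, z, s) and greater(y, z, s)):
                            label = f"{x},{y}>{z}"
                            break
        labels.append(label)

    sites = sites.copy()
    sites["label"] = labels
    vc = sites["label"].value_counts()
    retained_labels = {lab for lab, n in vc.items()
                       if lab != UNCLASSIFIED and n >= config.min_category}
    sites["retained"] = sites["label"].isin(retained_labels)
    for (a, b) in pdiff:
        sites[f"q_{a}_vs_{b}"] = qdiff[(a, b)]
    for tf in tf_names:
        sites[f"logfc_{tf}"] = logfc[tf]
    return CategorizedSites(sites=sites, pair_stats=pd.DataFrame(pair_rows),
                            counts=counts, dispersion=float(phi))


def classify_pairwise(events_a, events_b, libs_a, libs_b, input_lib,
                      config: TestConfig | None = None,
                      names=("A", "B")) -> CategorizedSites:
    return classify({names[0]: events_a, names[1]: events_b},
                    {names[0]: libs_a, names[1]: libs_b}, input_lib, config)


def classify_multiway(events_by_tf, libs_by_tf, input_lib,
                      config: TestConfig | None = None) -> CategorizedSites:
    return classify(events_by_tf, libs_by_tf, input_lib, config)


def match_to_truth(sites: pd.DataFrame, truth_sites: pd.DataFrame,
                   radius: int = 100) -> pd.Series:
    """For each classified site, the truth category of the nearest planted
    site within ``radius`` bp (NaN if none)."""
    out = pd.Series(np.nan, index=sites.index, dtype=object)
    for chrom, sub in sites.groupby("chrom"):
        tr = truth_sites[truth_sites.chrom == chrom].sort_values("point")
        if len(tr) == 0:
            continue
        tpts = tr["point"].to_numpy()
        tcat = tr["category"].to_numpy()
        pts = sub["point"].to_numpy()
        idx = np.clip(np.searchsorted(tpts, pts), 0, len(tpts) - 1)
        left = np.clip(idx - 1, 0, len(tpts) - 1)
        d_right = np.abs(tpts[idx] - pts)
        d_left = np.abs(tpts[left] - pts)
        best = np.where(d_left < d_right, left, idx)
        dist = np.minimum(d_left, d_right)
        vals = np.where(dist <= radius, tcat[best], None)
        out.loc[sub.index] = vals
    return out
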