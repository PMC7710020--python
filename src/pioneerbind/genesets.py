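"""Differential-expression gene sets and binding-category association.

Gene sets are built from LFC / adjusted-p summary tables with fixed
threshold rules (shared up/down across all TFs, TF-specific, and
two-of-three sets); peaks are assigned to the gene with the nearest TSS;
association between a binding category and a gene set is a logistic
regression of the per-gene bound indicator on set membership with a
log10 mappable-gene-length covariate, tested with the Wald statistic
and Benjamini-Hochberg correction across all category x set pairs.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


# --------------------------------------------------------------------------
# gene sets


class MissingContrastError(KeyError):
    pass


def _pivot(records: pd.DataFrame):
    lfc = records.pivot_table(index="gene", columns="contrast", values="lfc")
    padj = records.pivot_table(index="gene", columns="contrast", values="padj")
    return lfc, padj


def build_gene_sets(records: pd.DataFrame, tf_names=("A", "B", "C"),
                    baseline: str = "base", lfc_thresh: float = 2.0,
                    alpha: float = 0.01) -> dict[str, set]:
    """Deterministic gene-set assignment from an expression summary table.

    Expected contrasts: ``<TF>_vs_<baseline>`` for every TF plus every
    pairwise ``<X>_vs_<Y>``.  Rules per direction (up shown; down is the
    mirror image):

    - shared-up: LFC > t and padj < a versus baseline for every TF, and
      |LFC| <= t for every between-TF contrast (not differential).
    - <X>-up: X significantly above both other TFs (pairwise LFC > t,
      padj < a).
    - <X>+<Y>-up: X and Y each significantly above the third TF and not
      differential between themselves (|LFC| <= t).
    """
    tf_names = list(tf_names)
    lfc, padj = _pivot(records)
    needed = [f"{t}_vs_{baseline}" for t in tf_names]
    pair_cols = {}
    for x, y in combinations(tf_names, 2):
        if f"{x}_vs_{y}" in lfc.columns:
            pair_cols[(x, y)] = (f"{x}_vs_{y}", 1.0)
        elif f"{y}_vs_{x}" in lfc.columns:
            pair_cols[(x, y)] = (f"{y}_vs_{x}", -1.0)
        else:
            raise MissingContrastError(f"missing contrast {x}_vs_{y}")
    for col in needed:
        if col not in lfc.columns:
            raise MissingContrastError(f"missing contrast {col}")

    def pair_lfc(x, y):
        """LFC of x relative to y (sign-corrected)."""
        for (a, b), (col, sign) in pair_cols.items():
            if {a, b} == {x, y}:
                s = sign if a == x else -sign
                return lfc[col] * s, padj[col]
        raise MissingContrastError(f"{x} vs {y}")

    sets: dict[str, set] = {}
    for direction, up in (("up", 1.0), ("down", -1.0)):
        base_sig = {t: (up * lfc[f"{t}_vs_{baseline}"] > lfc_thresh)
                    & (padj[f"{t}_vs_{baseline}"] < alpha) for t in tf_names}
        pair_diff = {}
        pair_big = {}
        for x, y in combinations(tf_names, 2):
            pl, pp = pair_lfc(x, y)
            pair_big[(x, y)] = pl.abs() > lfc_thresh
            pair_diff[(x, y)] = (pl.abs() > lfc_thresh) & (pp < alpha)

        def not_diff(x, y):
            key = (x, y) if (x, y) in pair_big else (y, x)
            return ~pair_big[key]

        def sig_greater(x, y):
            pl, pp = pair_lfc(x, y)
            return (up * pl > lfc_thresh) & (pp < alpha)

        shared = base_sig[tf_names[0]].copy()
        for t in tf_names[1:]:
            shared &= base_sig[t]
        for x, y in combinations(tf_names, 2):
            shared &= not_diff(x, y)
        sets[f"shared-{direction}"] = set(shared.index[shared.fillna(False)])

        for x in tf_names:
            others = [t for t in tf_names if t != x]
            only = sig_greater(x, others[0]) & sig_greater(x, others[1])
            sets[f"{x}-{direction}"] = set(only.index[only.fillna(False)])

        for x, y in combinations(tf_names, 2):
            z = [t for t in tf_names if t not in (x, y)][0]
            two = (sig_greater(x, z) & sig_greater(y, z) & not_diff(x, y))
            sets[f"{x}+{y}-{direction}"] = set(two.index[two.fillna(False)])
    return sets


# --------------------------------------------------------------------------
# peak-to-gene assignment


def assign_peaks_to_genes(peaks: pd.DataFrame, genes: pd.DataFrame
                          ) -> tuple[pd.Series, pd.DataFrame]:
    """Assign each peak to the gene with the nearest TSS.

    Distance is |summit - TSS|; ties go to the lexicographically smaller
    gene id.  Peaks on chromosomes without genes are skipped.  Returns
    (per-gene bound indicator, peak assignment table).
    """
    bound = pd.Series(False, index=genes["gene"].to_numpy())
    rows = []
    for chrom, sub in peaks.groupby("chrom"):
        g = genes[genes.chrom == chrom].sort_values(
            ["tss", "gene"], kind="stable")
        if len(g) == 0:
            continue
        tss = g["tss"].to_numpy()
        ids = g["gene"].to_numpy()
        pts = sub["point"].to_numpy()
        right = np.clip(np.searchsorted(tss, pts), 0, len(tss) - 1)
        left = np.clip(right - 1, 0, len(tss) - 1)
        d_right = np.abs(tss[right] - pts)
        d_left = np.abs(tss[left] - pts)
        for i, pt in enumerate(pts):
            if d_left[i] < d_right[i]:
                gene = ids[left[i]]
            elif d_right[i] < d_left[i]:
                gene = ids[right[i]]
            else:
                gene = min(ids[left[i]], ids[right[i]])
            bound[gene] = True
            rows.append({"chrom": chrom, "point": int(pt), "gene": gene,
                         "distance": int(min(d_left[i], d_right[i]))})
    return bound, pd.DataFrame(rows, columns=["chrom", "point", "gene", "distance"])


# --------------------------------------------------------------------------
# association test


def association_test(bound: np.ndarray, membership: np.ndarray,
                     lengths: np.ndarray, tol: float = 1e-8) -> dict:
    """Logistic regression of bound ~ membership + log10(length).

    Returns the membership coefficient, its Wald p-value and a status
    ("ok" or "separation").  Perfect separation yields no p-value.
    """
    bound = np.asarray(bound, dtype=float)
    membership = np.asarray(membership, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if membership.sum() < 2 or (1 - membership).sum() < 2:
        raise ValueError("need >= 2 genes in and out of the set")
    if bound.min() == bound.max():
        raise ValueError("bound indicator has no variation")
    in_set = bound[membership == 1]
    if in_set.min() == in_set.max() and len(in_set) > 0:
        out_set = bound[membership == 0]
        if (in_set[0] == 1 and out_set.max() == 0) or \
           (in_set[0] == 0 and out_set.min() == 1):
            return {"beta": np.nan, "se": np.nan, "wald_p": np.nan,
                    "status": "separation"}
    X = np.column_stack([np.ones_like(bound), membership, np.log10(lengths)])
    try:
        model = sm.GLM(bound, X, family=sm.families.Binomial())
        res = model.fit(tol=tol, maxiter=200)
    except Exception:
        return {"beta": np.nan, "se": np.nan, "wald_p": np.nan,
                "status": "separation"}
    beta, se = float(res.params[1]), float(res.bse[1])
    if not np.isfinite(se) or abs(beta) > 15:
        return {"beta": beta, "se": se, "wald_p": np.nan, "status": "separation"}
    from scipy import stats as sps
    wald_p = float(2 * sps.norm.sf(abs(beta / se)))
    return {"beta": beta, "se": se, "wald_p": wald_p, "status": "ok"}


def association_matrix(category_peaks: dict[str, pd.DataFrame],
                       gene_sets: dict[str, set],
                       genes: pd.DataFrame) -> pd.DataFrame:
    """Wald test for every binding category x gene set pair; BH across
    the whole report."""
    ids = genes["gene"].to_numpy()
    lengths = genes["length"].to_numpy()
    rows = []
    for cat, peaks in category_peaks.items():
        bound, _ = assign_peaks_to_genes(peaks, genes)
        bvec = bound.loc[ids].to_numpy()
        for label, members in gene_sets.items():
            mvec = np.isin(ids, list(members))
            if mvec.sum() < 2 or (~mvec).sum() < 2:
                continue
            res = association_test(bvec, mvec, lengths)
            rows.append({"category": cat, "gene_set": label, **res})
    df = pd.DataFrame(rows)
    if len(df):
        ok = df["status"] == "ok"
        adj = np.full(len(df), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = bh_adjust(df.loc[ok, "wald_p"].to_numpy())
        df["padj"] = adj
    return df
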