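"""Single-cell downstream statistics on cluster labels.

Clustering itself is upstream; this module consumes a per-cell table
(sample, condition, cluster, QC metrics) and provides:

* QC filtering on gene count, UMI count, mitochondrial fraction and
  log10(genes)/log10(UMI);
* a condition-wise cluster-proportion permutation test with bootstrap
  confidence intervals on obs_log2FC = log2(prop_b / prop_a);
* Wilcoxon rank-sum marker detection (one cluster vs rest) with the usual
  fold-change and expressed-fraction pre-filters;
* a pseudo-bulk two-condition comparison pooling all cells per condition.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust


def qc_filter_cells(
    t: pd.DataFrame,
    genes: tuple[int, int] = (250, 7000),
    umi_min: int = 500,
    mito_max: float = 0.15,
    lgpu_min: float = 0.80,
) -> pd.DataFrame:
    """Keep cells meeting all four QC criteria; removal counts in ``attrs``.

    Criteria: ``genes[0] <= n_genes <= genes[1]``, ``n_umi > umi_min``,
    ``mito_fraction < mito_max``, ``log10_genes_per_umi > lgpu_min``.  A
    boolean ``doublet`` column, if present, is honoured as a fifth filter.
    """
    crit = {
        "n_genes": (t["n_genes"] >= genes[0]) & (t["n_genes"] <= genes[1]),
        "n_umi": t["n_umi"] > umi_min,
        "mito_fraction": t["mito_fraction"] < mito_max,
        "log10_genes_per_umi": t["log10_genes_per_umi"] > lgpu_min,
    }
    if "doublet" in t.columns:
        crit["doublet"] = ~t["doublet"].astype(bool)
    keep = np.logical_and.reduce([c.to_numpy() for c in crit.values()]) if len(t) else np.array([], bool)
    out = t.loc[keep].reset_index(drop=True)
    out.attrs["removed_per_criterion"] = {k: int((~c).sum()) for k, c in crit.items()}
    return out


def _cluster_counts(codes: np.ndarray, is_b: np.ndarray, n_clusters: int):
    cb = np.bincount(codes[is_b], minlength=n_clusters).astype(float)
    ca = np.bincount(codes[~is_b], minlength=n_clusters).astype(float)
    return ca, cb


def _log2fc(ca, cb, pseudo_mask):
    ca = np.where(pseudo_mask & (ca == 0), 1.0, ca)
    cb = np.where(pseudo_mask & (cb == 0), 1.0, cb)
    return np.log2((cb / cb.sum()) / (ca / ca.sum()))


def proportion_test(
    t: pd.DataFrame,
    n_perm: int = 1000,
    n_boot: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Cluster-proportion permutation test between two conditions.

    obs_log2FC compares the second condition (sorted order) against the
    first.  Condition labels are permuted over cells for the p-value
    ((b + 1)/(n + 1) smoothing); percentile bootstrap CIs resample cells
    with replacement within each condition.  Clusters absent from one
    condition receive a one-cell pseudo-count and are flagged.
    """
    conds = sorted(t["condition"].unique())
    if len(conds) != 2:
        raise ValueError(f"need exactly two conditions, got {conds}")
    clusters = sorted(t["cluster"].unique())
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    codes = pd.Categorical(t["cluster"], categories=clusters).codes.astype(int)
    is_b = (t["condition"] == conds[1]).to_numpy()
    K = len(clusters)
    n = len(t)
    rng = np.random.default_rng(seed)

    ca, cb = _cluster_counts(codes, is_b, K)
    pseudo = (ca == 0) | (cb == 0)
    obs = _log2fc(ca, cb, pseudo)

    exceed = np.zeros(K)
    for _ in range(n_perm):
        idx = rng.permutation(n)
        pa, pb = _cluster_counts(codes[idx], is_b, K)
        pm = pseudo | (pa == 0) | (pb == 0)
        perm = _log2fc(pa, pb, pm)
        exceed += np.abs(perm) >= np.abs(obs)
    pvalue = (exceed + 1.0) / (n_perm + 1.0)

    pa_hat = ca / ca.sum()
    pb_hat = cb / cb.sum()
    boot_a = rng.multinomial(int(ca.sum()), pa_hat, size=n_boot).astype(float)
    boot_b = rng.multinomial(int(cb.sum()), pb_hat, size=n_boot).astype(float)
    boot_a = np.where(boot_a == 0, 1.0, boot_a)
    boot_b = np.where(boot_b == 0, 1.0, boot_b)
    boot = np.log2(
        (boot_b / boot_b.sum(axis=1, keepdims=True))
        / (boot_a / boot_a.sum(axis=1, keepdims=True))
    )
    ci_low = np.percentile(boot, 2.5, axis=0)
    ci_high = np.percentile(boot, 97.5, axis=0)

    return pd.DataFrame(
        {
            "cluster": clusters,
            "prop_a": ca / ca.sum(),
            "prop_b": cb / cb.sum(),
            "obs_log2FC": obs,
            "pvalue": pvalue,
            "fdr": bh_adjust(pvalue),
            "ci_low": np.minimum(ci_low, obs),
            "ci_high": np.maximum(ci_high, obs),
            "pseudo_count_applied": pseudo,
        }
    )


def wilcoxon_markers(
    expr: pd.DataFrame,
    t: pd.DataFrame,
    lfc_thresh: float = 0.25,
    min_frac: float = 0.25,
    min_cells: int = 3,
) -> pd.DataFrame:
    """Per-cluster marker genes by Wilcoxon rank-sum vs all other cells.

    ``expr``: cells x genes (rows aligned to ``t``).  Genes enter the test
    only if |log2 fold of means| >= ``lfc_thresh`` and the expressed
    fraction (> 0) reaches ``min_frac`` on at least one side.  P-values are
    Bonferroni-adjusted by the total gene number.
    """
    if len(expr) != len(t):
        raise ValueError("expression rows must align with the cell table")
    X = expr.to_numpy(dtype=float)
    n_genes = X.shape[1]
    rows = []
    for cl in sorted(t["cluster"].unique()):
        inside = (t["cluster"] == cl).to_numpy()
        if inside.sum() < min_cells:
            warnings.warn(f"cluster {cl!r} has < {min_cells} cells; skipped", stacklevel=2)
            continue
        xi, xo = X[inside], X[~inside]
        mi, mo = xi.mean(axis=0), xo.mean(axis=0)
        lfc = np.log2((mi + 1.0) / (mo + 1.0))
        frac_i = (xi > 0).mean(axis=0)
        frac_o = (xo > 0).mean(axis=0)
        testable = (np.abs(lfc) >= lfc_thresh) & (np.maximum(frac_i, frac_o) >= min_frac)
        for j in np.flatnonzero(testable):
            p = float(stats.mannwhitneyu(xi[:, j], xo[:, j], alternative="two-sided").pvalue)
            rows.append({"cluster": cl, "gene": expr.columns[j], "log2fc": float(lfc[j]),
                         "frac_in": float(frac_i[j]), "frac_out": float(frac_o[j]),
                         "pvalue": p, "padj": min(1.0, p * n_genes)})
    return pd.DataFrame(rows, columns=["cluster", "gene", "log2fc", "frac_in",
                                       "frac_out", "pvalue", "padj"])


def pseudobulk_compare(expr: pd.DataFrame, t: pd.DataFrame, gene: str) -> tuple[float, float]:
    """Two-condition comparison of one gene pooling all cells per condition.

    Returns (log2fc of condition means with pseudo-count 1, Wilcoxon p).
    """
    if gene not in expr.columns:
        raise KeyError(f"gene {gene!r} absent from expression table")
    conds = sorted(t["condition"].unique())
    if len(conds) != 2:
        raise ValueError(f"need exactly two conditions, got {conds}")
    xa = expr.loc[(t["condition"] == conds[0]).to_numpy(), gene].to_numpy(dtype=float)
    xb = expr.loc[(t["condition"] == conds[1]).to_numpy(), gene].to_numpy(dtype=float)
    lfc = float(np.log2((xb.mean() + 1.0) / (xa.mean() + 1.0)))
    if np.array_equal(np.sort(xa), np.sort(xb)):
        return lfc, 1.0
    p = float(stats.mannwhitneyu(xb, xa, alternative="two-sided").pvalue)
    return lfc, p
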