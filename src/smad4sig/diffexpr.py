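"""Negative-binomial differential expression for genotype x time designs.

The workflow mirrors the standard count-based DE recipe for a small bulk
RNA-seq experiment (two genotypes, three time points, three replicates):

1. drop genes without at least ``min_reads`` reads in ``min_samples`` samples;
2. median-of-ratios size factors;
3. per-gene NB fit (profile-ML dispersion with a Cox-Reid adjustment, no
   empirical-Bayes shrinkage across genes) and a Wald z-test on the log2
   fold-change of a two-group contrast;
4. a likelihood-ratio test comparing nested designs for time-course effects;
5. Benjamini-Hochberg adjustment within each contrast.

Fold changes are reported unshrunk; an optional normal-prior shrinkage is
available via ``wald_test(..., shrink_lfc=sigma)`` for users who want
moderated estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import _nb

LN2 = np.log(2.0)

RESULT_COLUMNS = [
    "gene_id", "base_mean", "log2fc", "se_log2fc", "stat", "pvalue", "padj",
    "contrast",
]


class DesignError(ValueError):
    """Raised for invalid or non-nested design specifications."""


@dataclass
class CountMatrix:
    """Integer gene x sample counts plus aligned sample metadata.

    ``counts``: DataFrame indexed by gene id, columns are sample ids.
    ``sample_meta``: DataFrame indexed by sample id with at least
    ``genotype`` (WT/KO), ``time`` and ``replicate`` columns.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.sample_meta.index):
            raise ValueError("sample metadata rows must align 1:1 with count columns")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicated gene id: {dup!r}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def subset_samples(self, mask) -> "CountMatrix":
        cols = self.counts.columns[np.asarray(mask)]
        return CountMatrix(self.counts[cols], self.sample_meta.loc[cols])


def filter_low_counts(m: CountMatrix, min_reads: int = 5, min_samples: int = 3) -> CountMatrix:
    """Keep genes with at least ``min_reads`` reads in >= ``min_samples`` samples."""
    keep = (m.counts.to_numpy() >= min_reads).sum(axis=1) >= min_samples
    if not keep.any():
        warnings.warn("low-count filter removed every gene", stacklevel=2)
    return CountMatrix(m.counts.loc[keep], m.sample_meta)


def estimate_size_factors(m: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors against the geometric-mean pseudo-reference."""
    Y = m.counts.to_numpy(dtype=float)
    allpos = (Y > 0).all(axis=1)
    if not allpos.any():
        raise ValueError("no gene has nonzero counts in every sample; cannot normalize")
    logY = np.log(Y[allpos])
    logref = logY.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logY - logref, axis=0))
    return pd.Series(factors, index=m.sample_ids, name="size_factor")


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NaNs pass through."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    ps = p[ok]
    if (ps < 0).any() or (ps > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = ps.size
    if m == 0:
        return out
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    result = np.empty(m)
    result[order] = np.minimum(adj, 1.0)
    out[ok] = result
    return out


def _normalized(m: CountMatrix, size_factors: pd.Series | None) -> tuple[np.ndarray, np.ndarray]:
    sf = estimate_size_factors(m) if size_factors is None else size_factors.loc[m.sample_ids]
    sfv = sf.to_numpy(dtype=float)
    return m.counts.to_numpy(dtype=float) / sfv, sfv


def wald_test(
    m: CountMatrix,
    factor: str,
    test: str,
    ref: str,
    subset: dict | None = None,
    size_factors: pd.Series | None = None,
    contrast_label: str | None = None,
    shrink_lfc: float | None = None,
) -> pd.DataFrame:
    """Two-group NB Wald test of ``test`` vs ``ref`` levels of ``factor``.

    ``subset`` optionally restricts samples first (e.g. ``{"genotype": "WT"}``
    to compare time points within one genotype).  Size factors default to
    median-of-ratios on the full matrix so the contrast is computed on a
    consistent normalization.  ``shrink_lfc`` applies a zero-centred normal
    prior with that standard deviation (in log2 units) to the fold change.
    """
    if size_factors is None:
        size_factors = estimate_size_factors(m)
    sub = m
    if subset:
        mask = np.ones(len(m.sample_ids), dtype=bool)
        for col, val in subset.items():
            mask &= (m.sample_meta[col] == val).to_numpy()
        sub = m.subset_samples(mask)
    lv = sub.sample_meta[factor]
    in_test = (lv == test).to_numpy()
    in_ref = (lv == ref).to_numpy()
    if in_test.sum() < 2 or in_ref.sum() < 2:
        raise DesignError(f"each contrast group needs >= 2 samples ({factor}: {test} vs {ref})")
    keep = in_test | in_ref
    sub = sub.subset_samples(keep)
    codes = np.where((sub.sample_meta[factor] == test).to_numpy(), 1, 0)

    Y = sub.counts.to_numpy(dtype=float)
    sfv = size_factors.loc[sub.sample_ids].to_numpy(dtype=float)
    alpha = _nb.estimate_dispersion(Y, sfv, codes, 2)
    beta, info = _nb.fit_group_means(Y, sfv, codes, 2, alpha)

    norm = Y / sfv
    base_mean = norm.mean(axis=1)
    zero_group = (info <= 1e-12).any(axis=1)
    zero_both = Y.sum(axis=1) == 0

    log2fc = (beta[:, 1] - beta[:, 0]) / LN2
    # genes empty in one group: pseudo-count 0.5 on normalized group means
    if zero_group.any():
        mref = norm[:, codes == 0].mean(axis=1)
        mtest = norm[:, codes == 1].mean(axis=1)
        log2fc = np.where(zero_group, np.log2((mtest + 0.5) / (mref + 0.5)), log2fc)
    se = np.sqrt(1.0 / np.maximum(info[:, 0], 1e-8) + 1.0 / np.maximum(info[:, 1], 1e-8)) / LN2
    if shrink_lfc is not None:
        w = shrink_lfc**2 / (shrink_lfc**2 + se**2)
        log2fc = w * log2fc
    z = log2fc / se
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    log2fc = np.where(zero_both, 0.0, log2fc)
    z = np.where(zero_both, 0.0, z)
    pvalue = np.where(zero_both, 1.0, pvalue)

    label = contrast_label or f"{factor}:{test}_vs_{ref}"
    res = pd.DataFrame(
        {
            "gene_id": sub.gene_ids,
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se_log2fc": se,
            "stat": z,
            "pvalue": pvalue,
            "padj": bh_adjust(pvalue),
            "contrast": label,
        }
    ).reset_index(drop=True)
    res.attrs["zero_in_one_group"] = sub.gene_ids[zero_group & ~zero_both].tolist()
    res.attrs["zero_in_both_groups"] = sub.gene_ids[zero_both].tolist()
    return res


def _design_matrix(meta: pd.DataFrame, terms: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded design matrix for main-effect and ``a:b`` interaction terms."""
    cols: list[np.ndarray] = [np.ones(len(meta))]
    names = ["Intercept"]

    def main_dummies(name: str):
        levels = sorted(meta[name].astype(str).unique())
        out = []
        for lev in levels[1:]:
            out.append(((meta[name].astype(str) == lev).to_numpy(float), f"{name}[{lev}]"))
        return out

    for term in terms:
        if ":" in term:
            a, b = term.split(":")
            for da, na in main_dummies(a):
                for db, nb_ in main_dummies(b):
                    cols.append(da * db)
                    names.append(f"{na}:{nb_}")
        else:
            for d, nm in main_dummies(term):
                cols.append(d)
                names.append(nm)
    return np.column_stack(cols), names


def lrt_time_series(
    m: CountMatrix,
    full: tuple[str, ...] = ("genotype", "time", "genotype:time"),
    reduced: tuple[str, ...] = ("genotype", "time"),
    size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Likelihood-ratio test between nested NB log-linear designs.

    The default compares a genotype x time interaction model against the
    additive model, i.e. it asks which genes respond to the stimulus
    differently in the two genotypes.  Dispersion is estimated once per gene
    under the cell-means (full) grouping and held fixed in both fits.
    """
    if not set(reduced) <= set(full):
        raise DesignError(f"reduced design {reduced} is not nested in full design {full}")
    _, sfv = _normalized(m, size_factors)
    Y = m.counts.to_numpy(dtype=float)
    base_mean = (Y / sfv).mean(axis=1)

    Xf, names_f = _design_matrix(m.sample_meta, full)
    Xr, _ = _design_matrix(m.sample_meta, reduced)
    df = int(np.linalg.matrix_rank(Xf) - np.linalg.matrix_rank(Xr))
    if set(full) == set(reduced) or df == 0:
        stat = np.zeros(len(m.gene_ids))
        pvalue = np.ones_like(stat)
    else:
        factors = sorted({f for t in full for f in t.split(":")})
        cells = m.sample_meta[factors].astype(str).agg("|".join, axis=1)
        codes, uniques = pd.factorize(cells)
        alpha = _nb.estimate_dispersion(Y, sfv, codes, len(uniques))
        _, ll_full = _nb.fit_nb_glm(Y, Xf, sfv, alpha)
        _, ll_red = _nb.fit_nb_glm(Y, Xr, sfv, alpha)
        stat = np.maximum(2.0 * (ll_full - ll_red), 0.0)
        pvalue = stats.chi2.sf(stat, df)

    label = f"LRT:{'+'.join(full)}_vs_{'+'.join(reduced)}"
    return pd.DataFrame(
        {
            "gene_id": m.gene_ids,
            "base_mean": base_mean,
            "log2fc": np.nan,
            "se_log2fc": np.nan,
            "stat": stat,
            "pvalue": pvalue,
            "padj": bh_adjust(pvalue),
            "contrast": label,
        }
    ).reset_index(drop=True)


def call_deg(res: pd.DataFrame, lfc_thresh: float = 1.5, alpha: float = 0.05) -> pd.DataFrame:
    """Label genes up/down at |log2FC| >= ``lfc_thresh`` and padj < ``alpha``.

    The fold-change boundary is inclusive, the FDR boundary strict.
    """
    sig = res["padj"].to_numpy() < alpha
    up = sig & (res["log2fc"].to_numpy() >= lfc_thresh)
    down = sig & (res["log2fc"].to_numpy() <= -lfc_thresh)
    out = res.loc[up | down].copy()
    out["direction"] = np.where(out["log2fc"] >= lfc_thresh, "up", "down")
    return out.reset_index(drop=True)
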