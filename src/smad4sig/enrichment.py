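"""Rank-based gene-set enrichment with the CERNO statistic.

For a gene ranking (1 = most significant) and a module of k member genes,

    stat = -2 * sum_{g in module} ln(rank_g / N)  ~  chi-square(2k)

under the null of uniformly scattered ranks (a Fisher combination of the
uniform rank fractions).  Per module the rank-biserial AUC is also
reported: U / (n_in * n_out) from the member rank-sum, so a module packed
at the top of the ranking has AUC near 1.  BH adjustment runs across
modules; the standard positivity rule is AUC >= 0.5 and padj < alpha.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust


def rank_genes(res: pd.DataFrame, by: str = "pvalue", ascending: bool = True) -> list[str]:
    """Gene ids ordered most-significant first; ties keep original order."""
    order = res[by].to_numpy()
    idx = np.argsort(order if ascending else -order, kind="mergesort")
    return res["gene_id"].to_numpy()[idx].tolist()


def map_ranking(ranking: list[str], orthologs: pd.DataFrame) -> list[str]:
    """Translate a ranking through an ortholog map, dropping unmapped genes."""
    omap = orthologs.set_index("mouse_id")["human_id"].dropna().to_dict()
    mapped = [omap[g] for g in ranking if g in omap]
    return mapped


def cerno_test(ranking, modules: dict[str, list[str]]) -> pd.DataFrame:
    """CERNO test of every module against a gene ranking.

    ``ranking``: unique gene ids ordered from most to least significant.
    ``modules``: module_id -> member gene ids.  Modules with no member in
    the ranking get (n_found=0, NaN p); a module equal to the whole ranking
    has an undefined AUC (flagged NaN).
    """
    ranking = list(ranking)
    if len(set(ranking)) != len(ranking):
        raise ValueError("ranking contains duplicate genes")
    N = len(ranking)
    pos = {g: i + 1 for i, g in enumerate(ranking)}
    rows = []
    for mid, members in modules.items():
        ranks = np.array(sorted({pos[g] for g in members if g in pos}), dtype=float)
        k = len(ranks)
        if k == 0:
            rows.append({"module_id": mid, "cerno_stat": np.nan, "df": 0,
                         "pvalue": np.nan, "auc": np.nan, "n_found": 0})
            continue
        stat = float(-2.0 * np.log(ranks / N).sum())
        df = 2 * k
        p = float(stats.chi2.sf(stat, df))
        n_out = N - k
        if n_out == 0:
            auc = np.nan
        else:
            U = k * n_out + k * (k + 1) / 2.0 - ranks.sum()
            auc = float(U / (k * n_out))
        rows.append({"module_id": mid, "cerno_stat": stat, "df": df,
                     "pvalue": p, "auc": auc, "n_found": k})
    out = pd.DataFrame(rows)
    out["padj"] = bh_adjust(out["pvalue"]) if len(out) else []
    return out


def call_enriched(res: pd.DataFrame, auc_min: float = 0.5, alpha: float = 0.05) -> pd.DataFrame:
    """Positive modules: AUC >= ``auc_min`` and padj < ``alpha``."""
    if res.empty:
        return res.copy()
    keep = (res["auc"] >= auc_min) & (res["padj"] < alpha)
    return res.loc[keep.fillna(False)].reset_index(drop=True)
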