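"""Cross-species variant-context validation in a tumour cohort.

Given per-sample normalized expression, gene-level alteration calls and a
pathway catalog, this module: flags pathway variant status per sample,
selects the SMAD4-mutant and control groups, computes the mutant-vs-control
volcano (Mann-Whitney on each signature gene), assembles the four
variant-context subgroups

    G1 = SMAD4 wild-type, second-pathway variant absent
    G2 = SMAD4 wild-type, second-pathway variant present
    G3 = SMAD4 mutant,   second-pathway variant absent
    G4 = SMAD4 mutant,   second-pathway variant present

runs Kruskal-Wallis + Dunn/Holm across them, and applies the three-criterion
SMAD4-dependence rule:

1. expression differs between every SMAD4-WT vs SMAD4-mutant pair
   (G1-G3, G1-G4, G2-G3, G2-G4) in every tested context pathway;
2. no difference within mutation status (G1-G2 and G3-G4 non-significant);
3. the human mutant-vs-control direction matches the mouse direction.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .diffexpr import bh_adjust
from .synth import CohortTable

DEFAULT_PATHWAY_CATALOG = {
    "WNT": ["APC", "CTNNB1", "DKK1", "DKK2", "DKK3", "DKK4", "LRP5", "FZD10",
            "AMER1", "AXIN2", "TCF7L2", "FBXW7", "ARID1A"],
    "TP53": ["ATM", "TP53"],
    "PI3K": ["IGF2", "IRS2", "PTEN", "PIK3R1", "PIK3CA"],
    "RTK_RAS": ["NRAS", "KRAS", "BRAF", "ERBB2", "ERBB3"],
    "TGFB": ["ACVR1B", "ACVR2A", "SMAD2", "SMAD3", "SMAD4", "TGFBR1", "TGFBR2"],
    "BMP": ["SMAD1", "SMAD9", "SMAD5", "BMPR1A", "BMPR1B", "ACVR1"],
}

FLAG_COLUMNS = ("WNT", "SMAD4", "TGFB_other", "BMP", "RTK_RAS", "TP53", "PI3K")
PAIRS = ("G1G2", "G1G3", "G1G4", "G2G3", "G2G4", "G3G4")
CONTEXTS = ("RTK_RAS", "TP53", "PI3K")


def assign_pathway_status(c: CohortTable, catalog: dict | None = None) -> pd.DataFrame:
    """Per-sample boolean pathway flags from gene-level alteration calls.

    SMAD4 is flagged on its own; ``TGFB_other`` covers the remaining TGF-beta
    pathway genes so that "SMAD4 variant with no other pathway variant" is
    expressible downstream.
    """
    catalog = DEFAULT_PATHWAY_CATALOG if catalog is None else catalog
    unknown = set(catalog) - set(DEFAULT_PATHWAY_CATALOG)
    if unknown:
        raise ValueError(f"unknown pathway: {sorted(unknown)}")
    calls = c.variants
    out = {}
    for pathway, genes in catalog.items():
        present = [g for g in genes if g in calls.columns]
        hit = calls[present].any(axis=1) if present else pd.Series(False, index=calls.index)
        if pathway == "TGFB":
            non_smad4 = [g for g in present if g != "SMAD4"]
            out["TGFB_other"] = calls[non_smad4].any(axis=1) if non_smad4 else pd.Series(False, index=calls.index)
            out["SMAD4"] = calls["SMAD4"] if "SMAD4" in calls.columns else pd.Series(False, index=calls.index)
        else:
            out[pathway] = hit
    flags = pd.DataFrame(out, index=calls.index)
    for col in FLAG_COLUMNS:
        if col not in flags.columns:
            flags[col] = False
    return flags[list(FLAG_COLUMNS)]


def select_cohort(flags: pd.DataFrame) -> tuple[pd.Index, pd.Index]:
    """(SMAD4-mutant set, control set) under the cohort inclusion rules.

    Both groups must carry a WNT-pathway variant.  Mutant samples carry a
    SMAD4 variant and no other TGF-beta pathway variant; controls carry no
    TGF-beta pathway variant at all.
    """
    wnt = flags["WNT"]
    mutant = flags.index[wnt & flags["SMAD4"] & ~flags["TGFB_other"]]
    control = flags.index[wnt & ~flags["SMAD4"] & ~flags["TGFB_other"]]
    if len(mutant) == 0 or len(control) == 0:
        raise ValueError("mutant or control set is empty after cohort selection")
    return mutant, control


def volcano_mut_vs_wt(
    c: CohortTable, genes, mutant: pd.Index, control: pd.Index
) -> pd.DataFrame:
    """Per-gene Mann-Whitney mutant-vs-control with median log2 fold-change.

    log2FC = log2((median_mut + 1) / (median_ctrl + 1)); BH adjustment is
    applied across the supplied gene list only.
    """
    rows = []
    for g in genes:
        if g not in c.expression.columns:
            warnings.warn(f"gene {g!r} absent from expression table; skipped", stacklevel=2)
            continue
        xm = c.expression.loc[mutant, g].to_numpy(dtype=float)
        xc = c.expression.loc[control, g].to_numpy(dtype=float)
        if np.array_equal(np.sort(xm), np.sort(xc)):
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(xm, xc, alternative="two-sided").pvalue)
        lfc = float(np.log2((np.median(xm) + 1.0) / (np.median(xc) + 1.0)))
        rows.append({"gene": g, "median_log2fc": lfc, "pvalue": p})
    out = pd.DataFrame(rows, columns=["gene", "median_log2fc", "pvalue"])
    out["padj"] = bh_adjust(out["pvalue"]) if len(out) else []
    return out


def assemble_subgroups(
    flags: pd.DataFrame, mutant: pd.Index, control: pd.Index, context_pathway: str,
    min_group: int = 3,
) -> pd.Series:
    """Assign each selected sample to G1-G4 for one context pathway.

    Convention (recorded here once): odd groups lack the second-pathway
    variant, even groups carry it.
    """
    if context_pathway not in flags.columns:
        raise ValueError(f"unknown context pathway {context_pathway!r}")
    selected = mutant.append(control)
    ctx = flags.loc[selected, context_pathway]
    is_mut = pd.Series(selected.isin(mutant), index=selected)
    group = pd.Series(
        np.select(
            [~is_mut & ~ctx, ~is_mut & ctx, is_mut & ~ctx, is_mut & ctx],
            ["G1", "G2", "G3", "G4"],
            default="",
        ),
        index=selected,
        name=f"group[{context_pathway}]",
    )
    sizes = group.value_counts()
    for g in ("G1", "G2", "G3", "G4"):
        if sizes.get(g, 0) < min_group:
            raise ValueError(
                f"subgroup {g} has {sizes.get(g, 0)} samples (< {min_group}) "
                f"for context {context_pathway}"
            )
    return group


def kw_dunn(groups: list[np.ndarray]) -> tuple[float, float, dict]:
    """Kruskal-Wallis H (tie-corrected) plus Dunn pairwise z with Holm.

    Returns (H, kw_p, {pair_label: holm_adjusted_p}).  Pair labels follow
    the G1..G4 order of the input list.  If every observation is identical,
    the convention (H=0, p=1, all pairs p=1) applies.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 3 for g in groups):
        raise ValueError("each group needs at least 3 values")
    pooled = np.concatenate(groups)
    labels = [f"G{i + 1}" for i in range(len(groups))]
    pair_labels = [a + b for a, b in combinations(labels, 2)]
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0, {pl: 1.0 for pl in pair_labels}
    H, kw_p = stats.kruskal(*groups)

    # Dunn: z from pooled mid-ranks with tie correction
    N = len(pooled)
    ranks = stats.rankdata(pooled)
    splits = np.cumsum([len(g) for g in groups])[:-1]
    rank_groups = np.split(ranks, splits)
    rbar = np.array([rg.mean() for rg in rank_groups])
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (N - 1))
    sigma2 = N * (N + 1) / 12.0 - tie_term
    raw = []
    for (i, a), (j, b) in combinations(enumerate(groups), 2):
        se = np.sqrt(sigma2 * (1.0 / len(a) + 1.0 / len(b)))
        z = (rbar[i] - rbar[j]) / se
        raw.append(2.0 * stats.norm.sf(abs(z)))
    holm = multipletests(raw, method="holm")[1]
    return float(H), float(kw_p), dict(zip(pair_labels, holm))


def smad4_dependence_decision(
    pair_p: dict[str, dict[str, float]],
    kw_padj: dict[str, float],
    human_direction: float,
    mouse_direction: float,
    alpha: float = 0.05,
    mode: str = "all",
) -> tuple[bool, str]:
    """Apply the three-criterion rule for one gene.

    ``pair_p`` maps context pathway -> {pair: Holm-adjusted p}; ``kw_padj``
    maps context -> BH-adjusted Kruskal-Wallis p.  ``mode`` 'all' requires
    the criteria in every context, 'any' in at least one.
    Returns (smad4_dependent, failed_criterion in {'none','1','2','3'}).
    """
    if mode not in ("all", "any"):
        raise ValueError("mode must be 'all' or 'any'")
    contexts = list(pair_p)
    for ctx in contexts:
        missing = [pl for pl in PAIRS if pl not in pair_p[ctx]]
        if missing:
            raise ValueError(f"missing pairwise p-values {missing} for context {ctx}")

    def crit1(ctx):
        cross = ("G1G3", "G1G4", "G2G3", "G2G4")
        return kw_padj[ctx] < alpha and all(pair_p[ctx][pl] < alpha for pl in cross)

    def crit2(ctx):
        return pair_p[ctx]["G1G2"] >= alpha and pair_p[ctx]["G3G4"] >= alpha

    agg = all if mode == "all" else any
    if not agg(crit1(ctx) for ctx in contexts):
        return False, "1"
    if not agg(crit2(ctx) for ctx in contexts):
        return False, "2"
    if np.sign(human_direction) != np.sign(mouse_direction) or human_direction == 0:
        return False, "3"
    return True, "none"


def smad4_dependence_screen(
    c: CohortTable,
    genes,
    mouse_directions: dict[str, float],
    contexts=CONTEXTS,
    alpha: float = 0.05,
    mode: str = "all",
    catalog: dict | None = None,
) -> pd.DataFrame:
    """Run the full per-gene context analysis and dependence decision.

    For each context pathway the selected cohort is split into G1-G4,
    Kruskal-Wallis p-values are BH-adjusted across genes within the
    context, Dunn p-values are Holm-adjusted within each gene, and the
    three-criterion rule is applied (``mode='all'`` across contexts).
    """
    flags = assign_pathway_status(c, catalog)
    mutant, control = select_cohort(flags)
    genes = [g for g in genes if g in c.expression.columns]

    kw_raw: dict[str, list[float]] = {ctx: [] for ctx in contexts}
    pair_tbl: dict[str, list[dict]] = {ctx: [] for ctx in contexts}
    for ctx in contexts:
        group = assemble_subgroups(flags, mutant, control, ctx)
        by_group = {g: group.index[group == g] for g in ("G1", "G2", "G3", "G4")}
        for gene in genes:
            vals = [c.expression.loc[by_group[g], gene].to_numpy() for g in ("G1", "G2", "G3", "G4")]
            H, p, pairs = kw_dunn(vals)
            kw_raw[ctx].append(p)
            pair_tbl[ctx].append(pairs)
    kw_adj = {ctx: bh_adjust(kw_raw[ctx]) for ctx in contexts}

    vol = volcano_mut_vs_wt(c, genes, mutant, control).set_index("gene")
    rows = []
    for i, gene in enumerate(genes):
        pair_p = {ctx: pair_tbl[ctx][i] for ctx in contexts}
        kw_padj = {ctx: float(kw_adj[ctx][i]) for ctx in contexts}
        human_dir = float(np.sign(vol.loc[gene, "median_log2fc"]))
        dep, failed = smad4_dependence_decision(
            pair_p, kw_padj, human_dir, mouse_directions.get(gene, 0.0),
            alpha=alpha, mode=mode,
        )
        row = {"gene": gene, "smad4_dependent": dep, "failed_criterion": failed,
               "human_direction": human_dir,
               "mouse_direction": float(np.sign(mouse_directions.get(gene, 0.0)))}
        for ctx in contexts:
            row[f"kw_padj[{ctx}]"] = kw_padj[ctx]
            for pl in PAIRS:
                row[f"dunn[{ctx}][{pl}]"] = pair_p[ctx][pl]
        rows.append(row)
    return pd.DataFrame(rows)


def group_median_matrix(c: CohortTable, genes, context_pathway: str,
                        catalog: dict | None = None) -> pd.DataFrame:
    """Median log10 expression per subgroup per gene (heat-map input)."""
    flags = assign_pathway_status(c, catalog)
    mutant, control = select_cohort(flags)
    group = assemble_subgroups(flags, mutant, control, context_pathway)
    out = {}
    for g in ("G1", "G2", "G3", "G4"):
        idx = group.index[group == g]
        out[g] = np.log10(c.expression.loc[idx, [x for x in genes if x in c.expression.columns]]
                          .median(axis=0) + 1.0)
    return pd.DataFrame(out)
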