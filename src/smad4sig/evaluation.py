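"""Self-contained benchmark routines on the synthetic generators.

Each function simulates data with the bundled generators, runs the
corresponding analysis end to end, and returns summary numbers (calibration
rates, recovery rates, oracle statistics).  They back both the acceptance
checks and the reproducibility script; all randomness is seeded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import classify, cohort, diffexpr, enrichment, proportions, survival, synth
from .pipeline import build_contrast_set

T1_RESPONDERS = ("early_up", "early_down", "transient_up", "transient_down",
                 "smad4_dependent", "smad4_independent")


def wald_type1_error(n_genes: int = 2000, seed: int = 3, alpha: float = 0.05) -> float:
    """Type-I error of the Wald contrast on an all-null 3v3 simulation."""
    cfg = synth.BulkSimConfig(n_genes=n_genes, class_fractions={}, effect_lfc=0.0,
                              dispersion=0.1, seed=seed)
    cm, _ = synth.simulate_bulk_counts(cfg)
    res = diffexpr.wald_test(cm, "time", 1, 0, subset={"genotype": "WT"})
    return float((res["pvalue"] < alpha).mean())


def deg_recovery(n_genes: int = 2000, seed: int = 11) -> tuple[float, float]:
    """(sensitivity, FDR) of call_deg for planted log2fc=3 genes at 1 h."""
    cfg = synth.BulkSimConfig(n_genes=n_genes, effect_lfc=3.0, dispersion=0.1, seed=seed)
    cm, truth = synth.simulate_bulk_counts(cfg)
    res = diffexpr.wald_test(diffexpr.filter_low_counts(cm), "time", 1, 0,
                             subset={"genotype": "WT"})
    called = set(diffexpr.call_deg(res)["gene_id"])
    tested = set(res["gene_id"])
    positives = set(truth.loc[truth["class"].isin(T1_RESPONDERS), "gene_id"]) & tested
    sens = len(called & positives) / len(positives)
    fdr = len(called - positives) / max(len(called), 1)
    return float(sens), float(fdr)


def classifier_recovery(n_genes: int = 2000, seed: int = 11) -> dict:
    """Planted-label recovery of the full rule classifier.

    Returns per-class recovery, the pooled recovery over the checked
    classes, and the fraction of null genes receiving any label.
    """
    cfg = synth.BulkSimConfig(n_genes=n_genes, effect_lfc=3.0, dispersion=0.1, seed=seed)
    cm, truth = synth.simulate_bulk_counts(cfg)
    contrasts = build_contrast_set(diffexpr.filter_low_counts(cm))
    gc = classify.classify_targets(contrasts)
    m = gc.merge(truth, on="gene_id")
    checks = {
        "early_up": m["target_class"] == "early_up",
        "early_down": m["target_class"] == "early_down",
        "transient_up": m["target_class"] == "transient_up",
        "transient_down": m["target_class"] == "transient_down",
        "late_up": m["target_class"] == "late_up",
        "late_down": m["target_class"] == "late_down",
        "smad4_dependent": m["smad4_status"] == "dependent",
        "smad4_independent": m["smad4_status"] == "independent",
    }
    per_class, hit, tot = {}, 0, 0
    for cls, ok in checks.items():
        planted = m["class"] == cls
        per_class[cls] = float((ok & planted).sum() / max(planted.sum(), 1))
        hit += int((ok & planted).sum())
        tot += int(planted.sum())
    null = m[m["class"] == "null"]
    null_rate = float(((null["target_class"] != "none")
                       | (null["baseline_deg"] != "none")).mean())
    per_class["pooled"] = hit / tot
    per_class["null_labelled"] = null_rate
    return per_class


def cerno_oracle() -> tuple[float, float]:
    """CERNO stat and p for members at ranks {1, 2} of N=10."""
    res = enrichment.cerno_test([f"g{i}" for i in range(1, 11)], {"M": ["g1", "g2"]})
    return float(res.loc[0, "cerno_stat"]), float(res.loc[0, "pvalue"])


def cerno_null_ks(n_reps: int = 1000, n_genes: int = 500, seed: int = 0) -> float:
    """KS uniformity p-value of CERNO p under random rankings.

    The chi-square null is asymptotic in the ranking length: rank fractions
    are discrete and sampled without replacement, so short rankings (N ~ 100)
    show detectable discreteness; N=500 is comfortably in the regime where
    the approximation holds.
    """
    rng = np.random.default_rng(seed)
    genes = np.array([f"g{i}" for i in range(n_genes)])
    module = {"M": list(genes[:10])}
    pvals = [
        float(enrichment.cerno_test(list(rng.permutation(genes)), module).loc[0, "pvalue"])
        for _ in range(n_reps)
    ]
    return float(stats.kstest(pvals, "uniform").pvalue)


def cohort_decision_recovery(n_samples: int = 400, seed: int = 5) -> dict:
    """Sensitivity/specificity of the three-criterion screen on planted genes."""
    ct, truth = synth.simulate_cohort(synth.CohortSimConfig(n_samples=n_samples, seed=seed))
    genes = truth.loc[truth["class"] != "survival_cutpoint", "entity"].tolist()
    dirs = dict(zip(truth["entity"],
                    np.where(truth["effect"] == 0, 1.0, np.sign(truth["effect"]))))
    screen = cohort.smad4_dependence_screen(ct, genes, dirs)
    m = screen.merge(truth, left_on="gene", right_on="entity")
    dep = m[m["class"] == "smad4_dependent"]
    other = m[m["class"] != "smad4_dependent"]
    conf = m[m["class"] == "context_confounded"]
    return {
        "sensitivity": float(dep["smad4_dependent"].mean()),
        "specificity": float(1.0 - other["smad4_dependent"].mean()),
        "confounded_fail_1_or_2": float(conf["failed_criterion"].isin(["1", "2"]).mean()),
    }


def kw_oracle() -> float:
    """Kruskal-Wallis H on the four-group ranks-1..12 worked example."""
    groups = [np.array([1, 2, 3]), np.array([4, 5, 6]),
              np.array([7, 8, 9]), np.array([10, 11, 12])]
    H, _, _ = cohort.kw_dunn(groups)
    return float(H)


def maxstat_null_ks(n_sims: int = 500, n_perm: int = 200, n: int = 60, seed: int = 0) -> float:
    """KS uniformity p of the maxstat permutation p under the null."""
    pvals = []
    for i in range(n_sims):
        rng = np.random.default_rng(seed + i)
        x = rng.normal(size=n)
        t = rng.exponential(1.0, n)
        res = survival.maxstat_cutpoint(x, t, np.ones(n, int), n_perm=n_perm, seed=seed + i)
        pvals.append(res.pvalue)
    return float(stats.kstest(pvals, "uniform").pvalue)


def maxstat_recovery(n_reps: int = 100, n_samples: int = 200, seed: int = 300) -> float:
    """Fraction of replicates recovering the planted cut within (P30, P50)."""
    hits = 0
    for i in range(n_reps):
        ct, _ = synth.simulate_cohort(synth.CohortSimConfig(n_samples=n_samples, seed=seed + i))
        x = ct.expression["SURV1"].to_numpy()
        res = survival.maxstat_cutpoint(x, ct.survival["time"], ct.survival["event"],
                                        n_perm=20, seed=i)
        pct = (x <= res.cutpoint).mean()
        hits += 0.30 < pct < 0.50
    return hits / n_reps


def km_logrank_oracles() -> dict:
    """Closed-form product-limit and log-rank sanity values."""
    km = survival.km_estimate([1, 2, 3], [1, 1, 1])
    chi2_id, p_id = survival.logrank_test([1, 2, 3], [1, 1, 1], [1, 2, 3], [1, 1, 1])
    rng = np.random.default_rng(1)
    ta, tb = rng.exponential(1, 30), rng.exponential(2, 25)
    ea, eb = np.ones(30, int), np.ones(25, int)
    ab = survival.logrank_test(ta, ea, tb, eb)
    ba = survival.logrank_test(tb, eb, ta, ea)
    return {
        "km_surv": [float(v) for v in km.survival],
        "identical_chi2": float(chi2_id),
        "swap_chi2_diff": float(abs(ab[0] - ba[0])),
    }


def proportion_example() -> float:
    """obs_log2FC for the 10/100 vs 20/100 worked example."""
    rows = []
    for cond, (nx, nr) in {"A": (10, 90), "B": (20, 80)}.items():
        for cl, k in (("X", nx), ("rest", nr)):
            rows += [(f"{cond}{cl}{i}", cond, cond, cl, 1000, 3000, 0.05, 0.9)
                     for i in range(k)]
    t = pd.DataFrame(rows, columns=["cell_id", "sample_id", "condition", "cluster",
                                    "n_genes", "n_umi", "mito_fraction",
                                    "log10_genes_per_umi"])
    res = proportions.proportion_test(t, n_perm=50, n_boot=50, seed=0).set_index("cluster")
    return float(res.loc["X", "obs_log2FC"])


def proportion_type1(n_reps: int = 400, n_perm: int = 200, seed: int = 0,
                     alpha: float = 0.05) -> float:
    """Null rejection rate of the proportion permutation test."""
    rej = 0
    for i in range(n_reps):
        rng = np.random.default_rng(seed + i)
        rows = []
        for cond in ("A", "B"):
            k = rng.binomial(200, 0.3)
            rows += [(f"{cond}{j}", cond, cond, "X" if j < k else "Y",
                      1000, 3000, 0.05, 0.9) for j in range(200)]
        t = pd.DataFrame(rows, columns=["cell_id", "sample_id", "condition", "cluster",
                                        "n_genes", "n_umi", "mito_fraction",
                                        "log10_genes_per_umi"])
        res = proportions.proportion_test(t, n_perm=n_perm, n_boot=10, seed=seed + i)
        rej += bool(res.set_index("cluster").loc["X", "pvalue"] < alpha)
    return rej / n_reps
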