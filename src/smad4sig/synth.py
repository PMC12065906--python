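"""Synthetic data generators for every analysis stage.

Three simulators emit inputs with the statistical structure the downstream
methods assume, each paired with a truth table recording what was planted:

* ``simulate_bulk_counts`` -- NB counts for a 2-genotype x 3-timepoint x
  3-replicate organoid stimulation design with planted early / transient /
  late / Smad4-dependent / Smad4-independent / baseline-shift genes;
* ``simulate_cohort`` -- a tumour cohort with pathway variant flags,
  context-dependent expression shifts and survival times whose hazard
  depends on a planted expression cut-point;
* ``simulate_cells`` -- per-cell tables with condition-specific multinomial
  cluster compositions and QC metrics.

All generators are deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexpr import CountMatrix


class ConfigError(ValueError):
    """Raised for invalid simulator configurations."""


BULK_CLASSES = (
    "null", "early_up", "early_down", "transient_up", "transient_down",
    "late_up", "late_down", "smad4_dependent", "smad4_independent",
    "baseline_shift",
)

DEFAULT_CLASS_FRACTIONS = {
    "early_up": 0.03, "early_down": 0.03,
    "transient_up": 0.03, "transient_down": 0.03,
    "late_up": 0.03, "late_down": 0.03,
    "smad4_dependent": 0.04, "smad4_independent": 0.04,
    "baseline_shift": 0.04,
}


@dataclass
class BulkSimConfig:
    n_genes: int = 2000
    n_reps: int = 3
    timepoints: tuple = (0, 1, 12)
    genotypes: tuple = ("WT", "KO")
    mean_log_loc: float = 4.0      # log-normal location of per-gene NB means
    mean_log_scale: float = 1.0
    dispersion: float = 0.1
    effect_lfc: float = 3.0
    class_fractions: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS))
    size_factors: tuple | None = None   # optional per-sample scalar factors
    seed: int = 0

    def validate(self) -> None:
        fr = self.class_fractions
        unknown = set(fr) - set(BULK_CLASSES)
        if unknown:
            raise ConfigError(f"unknown gene classes: {sorted(unknown)}")
        if any(v < 0 for v in fr.values()) or sum(fr.values()) > 1 + 1e-9:
            raise ConfigError("class fractions must be >= 0 and sum to <= 1")
        if self.n_reps < 2:
            raise ConfigError("need at least 2 replicates per group")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be positive")


def _assign_classes(cfg: BulkSimConfig, rng: np.random.Generator) -> np.ndarray:
    counts = {c: int(round(f * cfg.n_genes)) for c, f in cfg.class_fractions.items() if f > 0}
    total = sum(counts.values())
    if total > cfg.n_genes:
        raise ConfigError("class fractions allocate more genes than n_genes")
    labels = np.array(
        [c for c, k in counts.items() for _ in range(k)] + ["null"] * (cfg.n_genes - total),
        dtype=object,
    )
    rng.shuffle(labels)
    return labels


def simulate_bulk_counts(config: BulkSimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """NB counts for the genotype x time design plus a per-gene truth table.

    Effect shapes (multiplicative on the NB mean, 2**effect_lfc):
    early: WT at 1 h and 12 h; transient: WT at 1 h only; late: WT at 12 h
    only; smad4_dependent: WT 1 h + 12 h (KO flat); smad4_independent:
    both genotypes 1 h + 12 h; baseline_shift: KO at all times.  ``_down``
    classes and the randomly-signed classes use the negated effect.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    t0, t1, t2 = config.timepoints
    gt = list(config.genotypes)
    groups = [(g, t) for g in gt for t in config.timepoints]
    samples = [
        (g, t, r)
        for (g, t) in groups
        for r in range(1, config.n_reps + 1)
    ]
    sample_ids = [f"{g}_t{t}_r{r}" for g, t, r in samples]
    meta = pd.DataFrame(
        {"genotype": [s[0] for s in samples],
         "time": [s[1] for s in samples],
         "replicate": [s[2] for s in samples]},
        index=pd.Index(sample_ids, name="sample_id"),
    )

    classes = _assign_classes(config, rng)
    base = rng.lognormal(config.mean_log_loc, config.mean_log_scale, config.n_genes)
    # signed planted effect: *_up / *_down fixed, remaining classes random sign
    sign = np.ones(config.n_genes)
    sign[np.char.endswith(classes.astype(str), "_down")] = -1.0
    random_sign = np.isin(classes, ["smad4_dependent", "smad4_independent", "baseline_shift"])
    sign[random_sign] = rng.choice([-1.0, 1.0], random_sign.sum())
    effect = np.where(classes == "null", 0.0, sign * config.effect_lfc)

    mult = np.ones((config.n_genes, len(groups)))
    fold = 2.0 ** effect
    for j, (g, t) in enumerate(groups):
        is_wt = g == gt[0]
        m = np.ones(config.n_genes)
        if t == t1:
            m = np.where(np.isin(classes, ["early_up", "early_down", "transient_up",
                                           "transient_down", "smad4_dependent"]) & is_wt,
                         fold, m)
            m = np.where(classes == "smad4_independent", fold, m)
        elif t == t2:
            m = np.where(np.isin(classes, ["early_up", "early_down", "late_up",
                                           "late_down", "smad4_dependent"]) & is_wt,
                         fold, m)
            m = np.where(classes == "smad4_independent", fold, m)
        if not is_wt:
            m = np.where(classes == "baseline_shift", fold * m, m)
        mult[:, j] = m

    sf = np.ones(len(samples)) if config.size_factors is None else np.asarray(config.size_factors, float)
    if sf.shape != (len(samples),):
        raise ConfigError("size_factors must have one entry per sample")
    group_of_sample = np.repeat(np.arange(len(groups)), config.n_reps)
    mu = base[:, None] * mult[:, group_of_sample] * sf[None, :]
    r = 1.0 / config.dispersion
    counts = rng.negative_binomial(r, r / (r + mu))

    gene_ids = pd.Index([f"g{i:05d}" for i in range(config.n_genes)], name="gene_id")
    cm = CountMatrix(pd.DataFrame(counts, index=gene_ids, columns=sample_ids), meta)
    truth = pd.DataFrame(
        {"gene_id": gene_ids, "class": classes, "effect_lfc": effect}
    ).reset_index(drop=True)
    return cm, truth


# ---------------------------------------------------------------------------
# cohort simulator

COHORT_PATHWAYS = ("WNT", "SMAD4", "TGFB_other", "BMP", "RTK_RAS", "TP53", "PI3K")
CONTEXT_PATHWAYS = ("RTK_RAS", "TP53", "PI3K")

DEFAULT_VARIANT_PREVALENCE = {
    "WNT": 0.95, "SMAD4": 0.30, "TGFB_other": 0.05, "BMP": 0.10,
    "RTK_RAS": 0.55, "TP53": 0.50, "PI3K": 0.45,
}


@dataclass
class CohortSimConfig:
    n_samples: int = 400
    n_genes: int = 60
    variant_prevalence: dict = field(default_factory=lambda: dict(DEFAULT_VARIANT_PREVALENCE))
    frac_dependent: float = 0.25
    frac_confounded: float = 0.25   # split evenly across the three context pathways
    dependent_gene_effect: float = 2.0
    context_gene_effect: float = 2.0
    base_log2_expr: float = 7.0
    noise_scale: float = 1.0
    survival_baseline_hazard: float = 0.05
    hazard_ratio: float = 4.0
    cut_quantile: float = 0.4
    censor_rate: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 8:
            raise ConfigError("n_samples < 8: subgroups unfillable")
        for k, v in self.variant_prevalence.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"prevalence for {k} outside [0, 1]")
        if self.survival_baseline_hazard <= 0 or self.hazard_ratio <= 0:
            raise ConfigError("hazard parameters must be positive")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ConfigError("censor_rate must lie in [0, 1)")


@dataclass
class CohortTable:
    """Per-sample normalized expression, gene-level variant calls and survival."""

    expression: pd.DataFrame       # samples x genes, positive RSEM-like values
    variants: pd.DataFrame         # samples x genes boolean alteration flags
    survival: pd.DataFrame         # sample_id index, columns time / event
    flags: pd.DataFrame | None = None   # per-sample pathway flags, filled later


def simulate_cohort(config: CohortSimConfig) -> tuple[CohortTable, pd.DataFrame]:
    """Cohort with planted SMAD4-dependent and context-confounded genes.

    Dependent genes shift (by ``dependent_gene_effect`` log2 units, random
    sign per gene) in every SMAD4-variant sample regardless of other
    variants; confounded genes shift only with their second-pathway variant;
    the remaining genes are null.  A dedicated ``SURV1`` gene carries a
    planted survival cut-point: samples above the ``cut_quantile`` threshold
    have their hazard multiplied by ``hazard_ratio``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = pd.Index([f"s{i:04d}" for i in range(n)], name="sample_id")

    flags = pd.DataFrame(
        {p: rng.random(n) < config.variant_prevalence.get(p, 0.0) for p in COHORT_PATHWAYS},
        index=sample_ids,
    )

    # gene panel
    n_dep = int(round(config.frac_dependent * config.n_genes))
    n_conf_each = int(round(config.frac_confounded * config.n_genes / len(CONTEXT_PATHWAYS)))
    genes, klass, context = [], [], []
    for i in range(n_dep):
        genes.append(f"DEP{i:03d}"); klass.append("smad4_dependent"); context.append("")
    for c in CONTEXT_PATHWAYS:
        for i in range(n_conf_each):
            genes.append(f"CONF_{c}_{i:03d}"); klass.append("context_confounded"); context.append(c)
    i = 0
    while len(genes) < config.n_genes:
        genes.append(f"NULL{i:03d}"); klass.append("null"); context.append(""); i += 1
    klass = np.array(klass, dtype=object)
    sign = rng.choice([-1.0, 1.0], len(genes))

    log2 = rng.normal(config.base_log2_expr, config.noise_scale, (n, len(genes)))
    smad4 = flags["SMAD4"].to_numpy()
    for j, (k, c) in enumerate(zip(klass, context)):
        if k == "smad4_dependent":
            log2[smad4, j] += sign[j] * config.dependent_gene_effect
        elif k == "context_confounded":
            log2[flags[c].to_numpy(), j] += sign[j] * config.context_gene_effect
    expr = pd.DataFrame(2.0 ** log2, index=sample_ids, columns=genes)

    # survival gene with a planted cut-point
    surv_expr = np.exp(rng.normal(np.log(100.0), 0.5, n))
    cut = float(np.quantile(surv_expr, config.cut_quantile))
    expr["SURV1"] = surv_expr
    high = surv_expr > cut
    lam = config.survival_baseline_hazard * np.where(high, config.hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / lam)
    if config.censor_rate > 0:
        lam_c = config.survival_baseline_hazard * config.censor_rate / (1.0 - config.censor_rate)
        t_cens = rng.exponential(1.0 / lam_c, n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    survival = pd.DataFrame({"time": time, "event": event}, index=sample_ids)

    # materialize gene-level variant calls consistent with the pathway flags
    from .cohort import DEFAULT_PATHWAY_CATALOG

    var_genes = sorted({g for gl in DEFAULT_PATHWAY_CATALOG.values() for g in gl})
    calls = pd.DataFrame(False, index=sample_ids, columns=var_genes)
    for p in COHORT_PATHWAYS:
        if p == "SMAD4":
            pool = ["SMAD4"]
        elif p == "TGFB_other":
            pool = [g for g in DEFAULT_PATHWAY_CATALOG["TGFB"] if g != "SMAD4"]
        else:
            pool = DEFAULT_PATHWAY_CATALOG[p]
        hit = flags[p].to_numpy()
        chosen = rng.choice(len(pool), size=n)
        for i in np.flatnonzero(hit):
            calls.iloc[i, calls.columns.get_loc(pool[chosen[i]])] = True

    truth_rows = [
        {"entity": g, "class": k, "effect": s * (config.dependent_gene_effect if k == "smad4_dependent"
                                                 else config.context_gene_effect if k == "context_confounded" else 0.0),
         "context": c}
        for g, k, s, c in zip(genes, klass, sign, context)
    ]
    truth_rows.append({"entity": "SURV1", "class": "survival_cutpoint",
                       "effect": config.hazard_ratio, "context": f"cut={cut:.6g}"})
    truth = pd.DataFrame(truth_rows)

    return CohortTable(expr, calls, survival, flags=None), truth


# ---------------------------------------------------------------------------
# single-cell table simulator

DEFAULT_CLUSTER_PROPORTIONS = {
    # condition -> cluster -> proportion; numbers follow the adenoma
    # composition the proportion test is meant to detect (progenitor
    # expansion and enterocyte depletion in the mutant)
    "WT": {"Pak3_high": 0.025, "Slc14a1_high": 0.035, "Lgr5_ISC": 0.058,
           "EC": 0.234, "Other": 0.648},
    "KO": {"Pak3_high": 0.105, "Slc14a1_high": 0.070, "Lgr5_ISC": 0.027,
           "EC": 0.078, "Other": 0.720},
}


@dataclass
class CellSimConfig:
    n_cells_per_sample: int = 1500
    n_samples_per_condition: int = 3
    cluster_proportions: dict = field(default_factory=lambda: {
        c: dict(v) for c, v in DEFAULT_CLUSTER_PROPORTIONS.items()})
    umi_log_mean: float = 8.3
    umi_log_sd: float = 0.4
    mito_beta: tuple = (2.0, 30.0)
    seed: int = 0

    def validate(self) -> None:
        if not self.cluster_proportions:
            raise ConfigError("empty cluster set")
        for cond, props in self.cluster_proportions.items():
            if not props:
                raise ConfigError(f"empty cluster set for condition {cond}")
            if abs(sum(props.values()) - 1.0) > 1e-6:
                raise ConfigError(f"cluster proportions for {cond} must sum to 1")


def simulate_cells(config: CellSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell table (sample, condition, cluster, QC metrics) + truth table."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows = []
    for cond, props in config.cluster_proportions.items():
        clusters = list(props)
        pvec = np.array([props[c] for c in clusters])
        for s in range(1, config.n_samples_per_condition + 1):
            k = rng.choice(len(clusters), size=config.n_cells_per_sample, p=pvec)
            umi = np.round(np.exp(rng.normal(config.umi_log_mean, config.umi_log_sd,
                                             config.n_cells_per_sample))).astype(int)
            umi = np.maximum(umi, 501)
            genes = np.round(10 ** (0.92 * np.log10(umi)
                                    + rng.normal(0.0, 0.04, config.n_cells_per_sample))).astype(int)
            genes = np.clip(genes, 1, None)
            mito = rng.beta(*config.mito_beta, config.n_cells_per_sample)
            sample = f"{cond}_s{s}"
            for i in range(config.n_cells_per_sample):
                rows.append((f"{sample}_c{i:05d}", sample, cond, clusters[k[i]],
                             genes[i], umi[i], mito[i]))
    t = pd.DataFrame(rows, columns=["cell_id", "sample_id", "condition", "cluster",
                                    "n_genes", "n_umi", "mito_fraction"])
    t["log10_genes_per_umi"] = np.log10(t["n_genes"]) / np.log10(t["n_umi"])
    truth = pd.DataFrame(
        [{"entity": cl, "class": f"proportion[{cond}]", "effect": p, "context": cond}
         for cond, props in config.cluster_proportions.items()
         for cl, p in props.items()]
    )
    return t, truth
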