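"""End-to-end demo pipeline chaining every analysis stage on synthetic data.

simulate -> differential expression (seven contrasts + time-course LRT) ->
target classification and cross-species signature -> rank enrichment ->
cohort context screen -> survival cut-point -> cluster proportions.

Each stage writes tab-separated artifacts under ``out_dir`` and the run
ends with a manifest (file -> sha256) so that reruns with the same seed can
be verified byte-identical.  Stage-level sub-seeds are derived from the
master seed so toggling stages does not perturb the others.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, cohort, diffexpr, enrichment, io, proportions, survival, synth

ALL_STAGES = ("simulate", "de", "classify", "enrich", "cohort", "survival", "proportions")

CONTRAST_SPECS = {
    "WT_t1_vs_t0": ("time", 1, 0, {"genotype": "WT"}),
    "WT_t12_vs_t0": ("time", 12, 0, {"genotype": "WT"}),
    "WT_t12_vs_t1": ("time", 12, 1, {"genotype": "WT"}),
    "KO_t1_vs_t0": ("time", 1, 0, {"genotype": "KO"}),
    "KO_t12_vs_t0": ("time", 12, 0, {"genotype": "KO"}),
    "KO_t12_vs_t1": ("time", 12, 1, {"genotype": "KO"}),
    "KO_vs_WT_t0": ("genotype", "KO", "WT", {"time": 0}),
}


@dataclass
class RunConfig:
    out_dir: str = "smad4sig_run"
    seed: int = 0
    n_genes: int = 400
    n_cohort_samples: int = 300
    n_cells_per_sample: int = 400
    lfc_thresh: float = 1.5
    alpha: float = 0.05
    signature_lfc: float = 2.0
    minprop: float = 0.1
    n_perm: int = 200
    n_boot: int = 200
    stages: tuple = ALL_STAGES

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw = io.read_config(path)
        kwargs = {}
        for f_ in cls.__dataclass_fields__.values():
            if f_.name not in raw:
                continue
            val = raw[f_.name]
            if f_.name == "stages":
                kwargs["stages"] = tuple(s.strip() for s in val.split(",") if s.strip())
            elif f_.type in ("int",):
                kwargs[f_.name] = int(val)
            elif f_.type in ("float",):
                kwargs[f_.name] = float(val)
            else:
                kwargs[f_.name] = val
        return cls(**kwargs)

    def validate(self) -> None:
        if self.lfc_thresh <= 0 or self.alpha <= 0 or self.minprop <= 0:
            raise ValueError("thresholds must be positive")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def _sub_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def build_contrast_set(cm, size_factors=None) -> dict[str, pd.DataFrame]:
    """Run the seven canonical contrasts of the genotype x time design."""
    if size_factors is None:
        size_factors = diffexpr.estimate_size_factors(cm)
    out = {}
    for label, (factor, test, ref, subset) in CONTRAST_SPECS.items():
        out[label] = diffexpr.wald_test(
            cm, factor, test, ref, subset=subset,
            size_factors=size_factors, contrast_label=label,
        )
    return out


def synthetic_ortholog_map(gene_ids, seed: int, mapped_fraction: float = 0.9) -> pd.DataFrame:
    """Synthetic mouse-to-human map: uppercase ids for a mapped subset."""
    rng = np.random.default_rng(seed)
    mapped = rng.random(len(gene_ids)) < mapped_fraction
    return pd.DataFrame({
        "mouse_id": list(gene_ids),
        "human_id": [g.upper() + "_HS" if m else None for g, m in zip(gene_ids, mapped)],
    })


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages; returns the manifest dict."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    log: list[str] = [f"seed={cfg.seed}", f"stages={','.join(cfg.stages)}"]

    def emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        artifacts.append(path)
        return path

    cm = truth = contrasts = None
    if "simulate" in cfg.stages:
        bulk_cfg = synth.BulkSimConfig(n_genes=cfg.n_genes, seed=_sub_seed(cfg.seed, "bulk"))
        cm, truth = synth.simulate_bulk_counts(bulk_cfg)
        io.write_counts(cm, out / "counts.tsv", out / "sample_meta.tsv")
        artifacts += [out / "counts.tsv", out / "sample_meta.tsv"]
        emit("truth_bulk.tsv", lambda p: io.write_table(truth, p))
        log.append(f"bulk: {cfg.n_genes} genes, effect_lfc={bulk_cfg.effect_lfc}")

    if "de" in cfg.stages:
        if cm is None:
            raise RuntimeError("stage 'de' requires stage 'simulate'")
        cm_f = diffexpr.filter_low_counts(cm)
        sf = diffexpr.estimate_size_factors(cm_f)
        contrasts = build_contrast_set(cm_f, sf)
        for label, res in contrasts.items():
            emit(f"de_{label}.tsv", lambda p, r=res: io.write_de_result(r, p))
        lrt = diffexpr.lrt_time_series(cm_f, size_factors=sf)
        emit("de_lrt.tsv", lambda p: io.write_de_result(lrt, p))
        log.append(f"de: lfc_thresh={cfg.lfc_thresh} alpha={cfg.alpha}")

    orthologs = None
    if "classify" in cfg.stages:
        if contrasts is None:
            raise RuntimeError("stage 'classify' requires stage 'de'")
        gene_classes = classify.classify_targets(contrasts, cfg.lfc_thresh, cfg.alpha)
        emit("gene_classes.tsv", lambda p: io.write_table(gene_classes, p))
        orthologs = synthetic_ortholog_map(
            contrasts["KO_vs_WT_t0"]["gene_id"], _sub_seed(cfg.seed, "orthologs"))
        emit("orthologs.tsv", lambda p: io.write_table(orthologs, p))
        sig = classify.baseline_signature(
            contrasts["KO_vs_WT_t0"], orthologs, cfg.signature_lfc, cfg.alpha)
        emit("signature.tsv", lambda p: io.write_table(sig, p))
        log.append(f"classify: signature_lfc={cfg.signature_lfc}")

    if "enrich" in cfg.stages:
        if contrasts is None or truth is None:
            raise RuntimeError("stage 'enrich' requires stages 'simulate' and 'de'")
        ranking = enrichment.rank_genes(contrasts["WT_t1_vs_t0"])
        modules = {
            f"planted_{k}": truth.loc[truth["class"] == k, "gene_id"].tolist()
            for k in sorted(truth["class"].unique()) if k != "null"
        }
        io.write_gmt(modules, out / "modules.gmt")
        artifacts.append(out / "modules.gmt")
        enr = enrichment.cerno_test(ranking, modules)
        emit("enrichment.tsv", lambda p: io.write_table(enr, p))
        log.append("enrich: auc_min=0.5")

    ct = cohort_truth = None
    if "cohort" in cfg.stages or "survival" in cfg.stages:
        ccfg = synth.CohortSimConfig(n_samples=cfg.n_cohort_samples,
                                     seed=_sub_seed(cfg.seed, "cohort"))
        ct, cohort_truth = synth.simulate_cohort(ccfg)
        io.write_cohort(ct, out / "cohort_expr.tsv", out / "cohort_variants.tsv",
                        out / "cohort_survival.tsv")
        artifacts += [out / "cohort_expr.tsv", out / "cohort_variants.tsv",
                      out / "cohort_survival.tsv"]
        emit("truth_cohort.tsv", lambda p: io.write_table(cohort_truth, p))

    if "cohort" in cfg.stages:
        sig_genes = cohort_truth.loc[
            cohort_truth["class"].isin(["smad4_dependent", "context_confounded", "null"]),
            "entity"].tolist()
        mouse_dirs = dict(zip(cohort_truth["entity"],
                              np.where(cohort_truth["effect"] == 0, 1.0,
                                       np.sign(cohort_truth["effect"]))))
        flags = cohort.assign_pathway_status(ct)
        mutant, control = cohort.select_cohort(flags)
        vol = cohort.volcano_mut_vs_wt(ct, sig_genes, mutant, control)
        emit("cohort_volcano.tsv", lambda p: io.write_table(vol, p))
        screen = cohort.smad4_dependence_screen(ct, sig_genes, mouse_dirs)
        emit("cohort_context.tsv", lambda p: io.write_table(screen, p))
        for ctx in cohort.CONTEXTS:
            med = cohort.group_median_matrix(ct, sig_genes, ctx)
            emit(f"cohort_heatmap_{ctx}.tsv", lambda p, m=med: io.write_table(m, p, index=True))
        log.append("cohort: groups G1-G4, odd=context-variant absent, even=present")

    if "survival" in cfg.stages:
        res = survival.maxstat_cutpoint(
            ct.expression["SURV1"].to_numpy(),
            ct.survival["time"].to_numpy(), ct.survival["event"].to_numpy(),
            minprop=cfg.minprop, n_perm=cfg.n_perm, seed=_sub_seed(cfg.seed, "maxstat"))
        cut_df = pd.DataFrame([{
            "gene": "SURV1", "cutpoint": res.cutpoint, "max_statistic": res.max_statistic,
            "pvalue": res.pvalue, "n_low": res.n_low, "n_high": res.n_high,
            "minprop": res.minprop,
        }])
        emit("survival_cutpoint.tsv", lambda p: io.write_table(cut_df, p))
        x = ct.expression["SURV1"].to_numpy()
        for side, mask in (("low", x <= res.cutpoint), ("high", x > res.cutpoint)):
            km = survival.km_estimate(ct.survival["time"].to_numpy()[mask],
                                      ct.survival["event"].to_numpy()[mask])
            emit(f"km_{side}.tsv", lambda p, k=km: io.write_table(k.as_frame(), p))
        log.append(f"survival: minprop={cfg.minprop} n_perm={cfg.n_perm}")

    if "proportions" in cfg.stages:
        cell_cfg = synth.CellSimConfig(n_cells_per_sample=cfg.n_cells_per_sample,
                                       seed=_sub_seed(cfg.seed, "cells"))
        cells, cell_truth = synth.simulate_cells(cell_cfg)
        emit("cells.tsv", lambda p: io.write_table(cells, p))
        emit("truth_cells.tsv", lambda p: io.write_table(cell_truth, p))
        filtered = proportions.qc_filter_cells(cells)
        prop = proportions.proportion_test(
            filtered, n_perm=cfg.n_perm, n_boot=cfg.n_boot,
            seed=_sub_seed(cfg.seed, "proportions"))
        emit("proportions.tsv", lambda p: io.write_table(prop, p))
        log.append(f"proportions: n_perm={cfg.n_perm} n_boot={cfg.n_boot}")

    (out / "run_log.txt").write_text("\n".join(log) + "\n")
    artifacts.append(out / "run_log.txt")
    manifest = {str(p.relative_to(out)): _sha256(p) for p in artifacts}
    io.write_json(manifest, out / "manifest.json")
    return manifest
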