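"""Rule-based classification of TGF-beta target genes.

From seven DE contrasts (time responses within each genotype plus the
baseline genotype contrast) each gene receives:

* a target class: early (responds at 1 h in the wild type), transient
  (early response that reverses toward/past baseline by 12 h), late
  (responds only at 12 h), or none;
* a Smad4 status: independent if the response is significant with the same
  sign in both genotypes relative to their own baselines, dependent if it
  occurs in the wild type only (or with opposite sign in the knockout);
* a baseline-DEG call from the knockout-vs-wild-type contrast at time 0,
  with the rule that a baseline difference opposing the TGF-beta response
  direction reassigns the gene as Smad4-dependent and removes it from the
  baseline list.

Precedence is transient > early > late; every gene gets exactly one class.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REQUIRED_CONTRASTS = (
    "WT_t1_vs_t0", "WT_t12_vs_t0", "WT_t12_vs_t1",
    "KO_t1_vs_t0", "KO_t12_vs_t0", "KO_t12_vs_t1",
    "KO_vs_WT_t0",
)


def _sig_table(res: pd.DataFrame, lfc_thresh: float, alpha: float) -> pd.DataFrame:
    t = res.set_index("gene_id")
    sig = (t["padj"] < alpha) & (t["log2fc"].abs() >= lfc_thresh)
    return pd.DataFrame({"sig": sig, "sign": np.sign(t["log2fc"])})


def classify_targets(
    contrasts: dict[str, pd.DataFrame],
    lfc_thresh: float = 1.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Assign target class, Smad4 status and baseline-DEG call per gene."""
    missing = [k for k in REQUIRED_CONTRASTS if k not in contrasts]
    if missing:
        raise ValueError(f"missing contrasts: {missing}")
    genes = contrasts["WT_t1_vs_t0"]["gene_id"]
    tabs = {k: _sig_table(v, lfc_thresh, alpha).reindex(genes) for k, v in contrasts.items()}

    def sig(k):
        return tabs[k]["sig"].fillna(False).to_numpy(dtype=bool)

    def sgn(k):
        return tabs[k]["sign"].fillna(0.0).to_numpy()

    early = sig("WT_t1_vs_t0")
    early_sign = sgn("WT_t1_vs_t0")
    # transient: early gene whose late comparison flips sign
    rev = (sig("WT_t12_vs_t0") & (sgn("WT_t12_vs_t0") == -early_sign)) | (
        sig("WT_t12_vs_t1") & (sgn("WT_t12_vs_t1") == -early_sign)
    )
    transient = early & rev
    late_any = sig("WT_t12_vs_t0") | sig("WT_t12_vs_t1")
    late = late_any & ~early
    late_sign = np.where(sig("WT_t12_vs_t0"), sgn("WT_t12_vs_t0"), sgn("WT_t12_vs_t1"))

    target_class = np.full(len(genes), "none", dtype=object)
    target_class[late] = np.where(late_sign[late] > 0, "late_up", "late_down")
    target_class[early] = np.where(early_sign[early] > 0, "early_up", "early_down")
    target_class[transient] = np.where(
        early_sign[transient] > 0, "transient_up", "transient_down"
    )

    response_sign = np.where(early, early_sign, np.where(late, late_sign, 0.0))

    # Smad4 status: independent needs a same-direction significant response
    # in the knockout against its own baseline
    ko_resp = (sig("KO_t1_vs_t0") & (sgn("KO_t1_vs_t0") == response_sign)) | (
        sig("KO_t12_vs_t0") & (sgn("KO_t12_vs_t0") == response_sign)
    )
    is_target = target_class != "none"
    smad4_status = np.full(len(genes), "not_applicable", dtype=object)
    smad4_status[is_target] = np.where(ko_resp[is_target], "independent", "dependent")

    baseline_sig = sig("KO_vs_WT_t0")
    baseline_sign = sgn("KO_vs_WT_t0")
    baseline = np.full(len(genes), "none", dtype=object)
    baseline[baseline_sig] = np.where(baseline_sign[baseline_sig] > 0, "up", "down")
    # baseline difference opposing the response direction: reassign dependent
    # and drop from the baseline list
    opposes = is_target & baseline_sig & (baseline_sign == -response_sign) & (response_sign != 0)
    smad4_status[opposes] = "dependent"
    baseline[opposes] = "none"
    # baseline-only DEGs reflect genotype-dependent expression
    baseline_only = ~is_target & (baseline != "none")
    smad4_status[baseline_only] = "dependent"

    ko_only = ~is_target & (sig("KO_t1_vs_t0") | sig("KO_t12_vs_t0"))

    return pd.DataFrame(
        {
            "gene_id": genes.to_numpy(),
            "target_class": target_class,
            "smad4_status": smad4_status,
            "baseline_deg": baseline,
            "ko_only_response": ko_only,
        }
    )


def baseline_signature(
    t0_contrast: pd.DataFrame,
    orthologs: pd.DataFrame,
    lfc_thresh: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Cross-species candidate signature from the baseline genotype contrast.

    Selects genes at |log2FC| >= ``lfc_thresh`` and padj < ``alpha``,
    annotates the human ortholog (two-column frame: mouse_id, human_id) and
    marks ``in_signature`` only for mapped genes; the fold-change sign is
    kept for later direction-concordance checks.
    """
    if orthologs["mouse_id"].duplicated().any():
        dup = orthologs.loc[orthologs["mouse_id"].duplicated(), "mouse_id"].iloc[0]
        raise ValueError(f"duplicate mouse id in ortholog map: {dup!r}")
    omap = orthologs.set_index("mouse_id")["human_id"]
    hits = t0_contrast[
        (t0_contrast["padj"] < alpha) & (t0_contrast["log2fc"].abs() >= lfc_thresh)
    ]
    human = hits["gene_id"].map(omap)
    return pd.DataFrame(
        {
            "mouse_id": hits["gene_id"].to_numpy(),
            "human_id": human.to_numpy(),
            "log2fc_sign": np.sign(hits["log2fc"]).to_numpy(),
            "in_signature": human.notna().to_numpy(),
        }
    ).reset_index(drop=True)
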