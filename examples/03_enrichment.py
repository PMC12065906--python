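"""CERNO rank enrichment of planted gene modules.

Ranks genes by the Wald contrast p-value and tests modules assembled from
the simulator's planted classes: modules of genuine responders should sit
at the top of the ranking (AUC near 1, tiny p), null modules should not.
"""

import smad4sig as s
from smad4sig.pipeline import build_contrast_set

cm, truth = s.simulate_bulk_counts(s.BulkSimConfig(n_genes=800, seed=21))
contrasts = build_contrast_set(s.filter_low_counts(cm))
ranking = s.rank_genes(contrasts["WT_t1_vs_t0"])

modules = {f"planted_{k}": truth.loc[truth["class"] == k, "gene_id"].tolist()
           for k in ("early_up", "late_up", "null")}
res = s.cerno_test(ranking, modules)
print(res[["module_id", "cerno_stat", "df", "pvalue", "padj", "auc", "n_found"]]
      .round(4).to_string(index=False))
positive = s.call_enriched(res, auc_min=0.5, alpha=0.05)
print("positive modules:", list(positive["module_id"]))
# early_up responds at 1 h, so it is enriched in this ranking; late_up only
# responds at 12 h and the null module scatters uniformly.
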