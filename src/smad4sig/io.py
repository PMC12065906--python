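"""Readers and writers for every table type, all plain tab-separated text.

Counts are genes x samples with a header row of sample ids and the gene id
in the first column; metadata, truth, DE-result, cohort, survival and cell
tables are ordinary TSVs.  Gene sets use the GMT dialect
(module_id <tab> description <tab> member...).  Every writer/reader pair
round-trips exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .diffexpr import CountMatrix
from .synth import CohortTable

FLOAT_FMT = "%.10g"


class ParseError(ValueError):
    pass


# -- count matrices ---------------------------------------------------------

def write_counts(m: CountMatrix, counts_path, meta_path) -> None:
    m.counts.to_csv(counts_path, sep="\t")
    m.sample_meta.to_csv(meta_path, sep="\t")


def read_counts(counts_path, meta_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    if counts.index.duplicated().any():
        dup = counts.index[counts.index.duplicated()][0]
        raise ParseError(f"duplicate gene id {dup!r} in {counts_path}")
    vals = counts.to_numpy()
    if not np.issubdtype(vals.dtype, np.number) or not np.allclose(vals, np.round(vals)):
        bad = counts.columns[0]
        raise ParseError(f"non-integer counts in {counts_path} (column {bad!r})")
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return CountMatrix(counts.astype(np.int64), meta)


def write_mtx(m: CountMatrix, mtx_path, genes_path, samples_path) -> None:
    """Sparse MatrixMarket coordinate output with companion id files."""
    from scipy import io as spio
    from scipy.sparse import csr_matrix

    spio.mmwrite(str(mtx_path), csr_matrix(m.counts.to_numpy()))
    Path(genes_path).write_text("\n".join(m.gene_ids) + "\n")
    Path(samples_path).write_text("\n".join(m.sample_ids) + "\n")


def read_mtx(mtx_path, genes_path, samples_path, meta_path=None) -> CountMatrix:
    from scipy import io as spio

    mat = spio.mmread(str(mtx_path)).toarray().astype(np.int64)
    genes = Path(genes_path).read_text().splitlines()
    samples = Path(samples_path).read_text().splitlines()
    counts = pd.DataFrame(mat, index=pd.Index(genes, name="gene_id"), columns=samples)
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    else:
        meta = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    return CountMatrix(counts, meta)


# -- generic tables ---------------------------------------------------------

def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


DE_COLUMNS = ["gene_id", "base_mean", "log2fc", "se_log2fc", "stat", "pvalue",
              "padj", "contrast"]


def write_de_result(res: pd.DataFrame, path) -> None:
    res[DE_COLUMNS].to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_de_result(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"DE result {path} missing columns {missing}")
    for c in DE_COLUMNS[1:-1]:
        df[c] = df[c].astype(float)
    return df


# -- cohort -----------------------------------------------------------------

def write_cohort(c: CohortTable, expr_path, variants_path, survival_path) -> None:
    c.expression.to_csv(expr_path, sep="\t", float_format=FLOAT_FMT)
    long = c.variants.stack()
    long = long[long].reset_index()
    long.columns = ["sample_id", "gene", "altered"]
    long[["sample_id", "gene"]].to_csv(variants_path, sep="\t", index=False)
    c.survival.to_csv(survival_path, sep="\t", float_format=FLOAT_FMT)


def read_cohort(expr_path, variants_path, survival_path, variant_genes=None) -> CohortTable:
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    surv = pd.read_csv(survival_path, sep="\t", index_col=0)
    long = pd.read_csv(variants_path, sep="\t")
    genes = variant_genes if variant_genes is not None else sorted(long["gene"].unique())
    calls = pd.DataFrame(False, index=expr.index, columns=genes)
    for _, row in long.iterrows():
        if row["gene"] in calls.columns and row["sample_id"] in calls.index:
            calls.loc[row["sample_id"], row["gene"]] = True
    return CohortTable(expr, calls, surv)


# -- gene sets --------------------------------------------------------------

def read_gmt(path) -> dict[str, list[str]]:
    modules: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}:{lineno}: GMT line needs id, description, members")
        mid = parts[0]
        if mid in modules:
            raise ParseError(f"{path}:{lineno}: duplicate module id {mid!r}")
        modules[mid] = [g for g in parts[2:] if g]
    return modules


def write_gmt(modules: dict[str, list[str]], path, descriptions=None) -> None:
    lines = []
    for mid, members in modules.items():
        desc = (descriptions or {}).get(mid, "na")
        lines.append("\t".join([mid, desc, *members]))
    Path(path).write_text("\n".join(lines) + "\n")


# -- ortholog map -----------------------------------------------------------

def read_orthologs(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["mouse_id", "human_id"]:
        df.columns = ["mouse_id", "human_id", *df.columns[2:]]
    if df["mouse_id"].duplicated().any():
        dup = df.loc[df["mouse_id"].duplicated(), "mouse_id"].iloc[0]
        raise ParseError(f"duplicate mouse id {dup!r} in ortholog map {path}")
    return df[["mouse_id", "human_id"]]


# -- flat key=value config --------------------------------------------------

def read_config(path) -> dict[str, str]:
    cfg = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        if "=" not in s:
            raise ParseError(f"{path}:{lineno}: expected key=value")
        k, v = s.split("=", 1)
        cfg[k.strip()] = v.strip()
    return cfg


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
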