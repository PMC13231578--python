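"""Readers and writers for the pipeline's plain-text formats.

Counts as TSV (genes in rows) or MatrixMarket MTX with row/column sidecars;
designs and contrast tables as TSV; Ct tables as CSV; gene sets as GMT;
truth and manifests as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_counts_mtx(counts: pd.DataFrame, prefix) -> None:
    """MTX plus `.rownames.txt` / `.colnames.txt` sidecars."""
    prefix = Path(prefix)
    spio.mmwrite(str(prefix.with_suffix(".mtx")), sparse.csr_matrix(counts.to_numpy()))
    prefix.with_suffix(".rownames.txt").write_text("\n".join(map(str, counts.index)) + "\n")
    prefix.with_suffix(".colnames.txt").write_text("\n".join(map(str, counts.columns)) + "\n")


def read_counts_mtx(prefix) -> pd.DataFrame:
    prefix = Path(prefix)
    mat = spio.mmread(str(prefix.with_suffix(".mtx")))
    rows = prefix.with_suffix(".rownames.txt").read_text().splitlines()
    cols = prefix.with_suffix(".colnames.txt").read_text().splitlines()
    dense = mat.toarray() if sparse.issparse(mat) else np.asarray(mat)
    return pd.DataFrame(dense, index=rows, columns=cols)


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_design(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_contrast_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="gene_id")


def read_contrast_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_ct_table(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def read_ct_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_gmt(path) -> dict[str, list[str]]:
    from gseapy import read_gmt as _read_gmt

    return _read_gmt(str(path))


def write_gmt(gene_sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def write_truth_json(truth, path) -> None:
    payload = {
        "seed": truth.seed,
        "gene_ids": truth.gene_ids,
        "baseline_log2_mean": truth.baseline_log2_mean.tolist(),
        "dispersion": truth.dispersion.tolist(),
        "donor_effects": truth.donor_effects.to_dict(orient="list"),
        "tnf_log2fc": truth.tnf_log2fc.to_dict(orient="list"),
        "spd1_log2fc": truth.spd1_log2fc.to_dict(orient="list"),
        "ligand_dependency": list(map(str, truth.ligand_dependency)),
        "library_sizes": truth.library_sizes.to_dict(),
        "responsive_genes": truth.responsive_genes,
    }
    Path(path).write_text(json.dumps(payload))


def read_truth_json(path):
    from .simdata import SyntheticTruth

    d = json.loads(Path(path).read_text())
    gene_ids = d["gene_ids"]
    return SyntheticTruth(
        gene_ids=gene_ids,
        baseline_log2_mean=np.asarray(d["baseline_log2_mean"]),
        dispersion=np.asarray(d["dispersion"]),
        donor_effects=pd.DataFrame(d["donor_effects"], index=gene_ids),
        tnf_log2fc=pd.DataFrame(d["tnf_log2fc"], index=gene_ids),
        spd1_log2fc=pd.DataFrame(d["spd1_log2fc"], index=gene_ids),
        ligand_dependency=np.asarray(d["ligand_dependency"], dtype=object),
        library_sizes=pd.Series(d["library_sizes"]),
        seed=d["seed"],
        responsive_genes=d.get("responsive_genes", {}),
    )


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify))


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
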