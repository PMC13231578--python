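"""Public-cohort utilities: single-cell QC, pseudobulk, GSVA, correlations.

Cells with fewer than 1000 detected genes or more than 25% mitochondrial
reads are removed; percent-expressing is the share of non-zero cells;
pseudobulk sums cells per sample and transforms to log2-CPM; single-sample
gene-set enrichment follows the GSVA recipe (Gaussian-kernel CDF, per-sample
ranking, weighted random walk, signed-difference score); Spearman
correlations are banded by the conventional strength cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats

from . import normcore

MIN_GENES = 1000
MAX_MITO = 0.25
MIN_UMI = 10

BANDS = ((0.2, "negligible"), (0.4, "weak"), (0.6, "moderate"), (0.8, "strong"))


def _cell_matrix(adata):
    x = adata.X
    return x.toarray() if sparse.issparse(x) else np.asarray(x)


def cell_qc_table(adata, min_genes: int = MIN_GENES, max_mito: float = MAX_MITO) -> pd.DataFrame:
    """Per-cell genes-detected, mitochondrial fraction and pass flag."""
    x = _cell_matrix(adata)
    is_mito = np.array([str(g).startswith("MT-") for g in adata.var_names])
    detected = (x > 0).sum(axis=1)
    total = x.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito = np.where(total > 0, x[:, is_mito].sum(axis=1) / total, 0.0)
    return pd.DataFrame(
        {
            "genes_detected": detected.astype(int),
            "mito_fraction": mito,
            "pass": (detected >= min_genes) & (mito <= max_mito),
        },
        index=adata.obs_names,
    )


def qc_filter_cells(
    adata,
    min_genes: int = MIN_GENES,
    max_mito: float = MAX_MITO,
    min_umi: int = MIN_UMI,
):
    """Remove low-quality cells and low-UMI genes.

    Cells fail with fewer than ``min_genes`` detected genes or a
    mitochondrial fraction strictly above ``max_mito`` (a fraction exactly
    at the cutoff is retained). Genes with total UMI below ``min_umi``
    across retained cells are then removed. Returns (filtered AnnData,
    per-cell QC table, report dict).
    """
    qc = cell_qc_table(adata, min_genes=min_genes, max_mito=max_mito)
    kept = adata[qc["pass"].to_numpy()].copy()
    x = _cell_matrix(kept)
    gene_ok = x.sum(axis=0) >= min_umi
    report = {
        "n_cells_in": adata.n_obs,
        "n_cells_removed_genes": int((qc["genes_detected"] < min_genes).sum()),
        "n_cells_removed_mito": int((qc["mito_fraction"] > max_mito).sum()),
        "n_cells_removed": int((~qc["pass"]).sum()),
        "n_genes_removed_umi": int((~gene_ok).sum()),
    }
    return kept[:, gene_ok].copy(), qc, report


def percent_expressing(adata, gene: str, groupby: str) -> pd.Series:
    """Share of cells with count > 0 for a gene, per group."""
    if gene not in adata.var_names:
        raise ValueError(f"gene {gene!r} not present")
    col = _cell_matrix(adata[:, gene]).ravel()
    groups = adata.obs[groupby]
    return pd.Series(col > 0, index=adata.obs_names).groupby(groups.to_numpy()).mean()


def pseudobulk(adata, sample_key: str = "sample_id", prior_count: float = 0.5) -> pd.DataFrame:
    """Sum cells per sample and transform to log2-CPM (factors 1)."""
    x = _cell_matrix(adata)
    samples = adata.obs[sample_key]
    sums = pd.DataFrame(x, index=adata.obs_names, columns=adata.var_names).groupby(
        samples.to_numpy()
    ).sum()
    counts = sums.T  # genes x samples
    return normcore.log2_cpm(counts, prior_count=prior_count)


def pseudobulk_group_test(
    pb: pd.DataFrame, gene: str, group_labels: pd.Series
) -> dict:
    """Mann-Whitney U two-group comparison of one gene's pseudobulk values.

    Exact enumeration below 8 per group, normal approximation with tie
    correction otherwise.
    """
    labels = group_labels.reindex(pb.columns)
    levels = sorted(set(labels.dropna()))
    if len(levels) != 2:
        raise ValueError("group_labels must define exactly two groups")
    a = pb.loc[gene, labels == levels[0]].to_numpy()
    b = pb.loc[gene, labels == levels[1]].to_numpy()
    method = "exact" if min(len(a), len(b)) < 8 else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {"u": float(res.statistic), "p": float(res.pvalue),
            "groups": levels, "n": (len(a), len(b))}


def gene_set_score(
    log2cpm: pd.DataFrame, gene_set: list[str], tau: float = 1.0
) -> pd.Series:
    """Single-sample gene-set enrichment scores (GSVA recipe).

    Per gene, a Gaussian-kernel cumulative density across samples
    (bandwidth = per-gene sd / 4); per sample, genes are ranked by the
    transformed values and scored by a weighted random walk (symmetric rank
    statistic to the power tau inside the set, uniform penalty outside);
    the score is the largest positive deviation minus the magnitude of the
    largest negative deviation.
    """
    genes = list(log2cpm.index)
    in_set = np.array([g in set(gene_set) for g in genes])
    if not in_set.any():
        raise ValueError("gene set has empty intersection with the matrix")
    if log2cpm.shape[1] < 3:
        raise ValueError("need at least 3 samples for enrichment scoring")
    x = log2cpm.to_numpy(dtype=float)
    p, n = x.shape
    sd = x.std(axis=1, ddof=1)
    h = np.where(sd > 0, sd / 4.0, 1e-8)
    # kernel CDF: z_ij = mean_k Phi((x_ij - x_ik) / h_i)
    z = stats.norm.cdf((x[:, :, None] - x[:, None, :]) / h[:, None, None]).mean(axis=2)

    m = int(in_set.sum())
    scores = np.empty(n)
    for j in range(n):
        order = np.argsort(-z[:, j], kind="stable")  # decreasing
        set_sorted = in_set[order]
        w = np.where(set_sorted, np.abs(p / 2.0 - np.arange(1, p + 1)) ** tau, 0.0)
        denom = w.sum()
        step_in = w / denom if denom > 0 else np.zeros(p)
        step_out = (~set_sorted).astype(float) / (p - m) if p > m else np.zeros(p)
        v = np.cumsum(step_in - step_out)
        scores[j] = max(v.max(), 0.0) + min(v.min(), 0.0)
    return pd.Series(scores, index=log2cpm.columns, name="enrichment_score")


def strength_band(rho: float) -> str:
    """Correlation strength bands on |rho| (0.2 / 0.4 / 0.6 / 0.8 cuts)."""
    a = abs(rho)
    for cut, name in BANDS:
        if a < cut:
            return name
    return "very strong"


@dataclass
class EnrichmentResult:
    rho: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    strength_band: str


def correlate_with_marker(
    scores: pd.Series, marker_expression: pd.Series
) -> EnrichmentResult:
    """Spearman rho with Fisher-z 95% CI and strength band."""
    paired = pd.concat([scores, marker_expression], axis=1, join="inner").dropna()
    if len(paired) < 4:
        raise ValueError("need at least 4 paired observations")
    rho, p = stats.spearmanr(paired.iloc[:, 0], paired.iloc[:, 1])
    n = len(paired)
    z = np.arctanh(np.clip(rho, -0.999999, 0.999999))
    se = 1.0 / np.sqrt(n - 3)
    lo, hi = np.tanh(z - 1.959964 * se), np.tanh(z + 1.959964 * se)
    return EnrichmentResult(
        rho=float(rho), ci_low=float(lo), ci_high=float(hi), p=float(p),
        n=n, strength_band=strength_band(rho),
    )


class GSVAScorer:
    """sklearn-style transformer: log2-CPM (samples x genes) → set scores.

    Stateless beyond its parameters; ``transform`` returns one enrichment
    score per sample for each configured gene set.
    """

    def __init__(self, gene_sets: dict[str, list[str]], tau: float = 1.0):
        self.gene_sets = gene_sets
        self.tau = tau

    def get_params(self, deep: bool = True) -> dict:
        return {"gene_sets": self.gene_sets, "tau": self.tau}

    def set_params(self, **params) -> "GSVAScorer":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: pd.DataFrame, y=None) -> "GSVAScorer":
        self.gene_names_ = list(X.columns)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = {
            name: gene_set_score(X.T, genes, tau=self.tau)
            for name, genes in self.gene_sets.items()
        }
        return pd.DataFrame(out)

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)
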