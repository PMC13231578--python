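"""Donor-blocked differential expression with empirical Bayes moderation.

Linear models per gene with condition (and disease-group interaction)
effects, a shared intra-donor "consensus" correlation handled by generalized
least squares under a block-exchangeable covariance, empirical Bayes
shrinkage of residual variances, moderated t contrasts and Benjamini-
Hochberg correction. The three primary contrasts compare TNF and TNF+sPD1
against control and each other; two further contrasts compare each ligand
knockout against TNF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from . import normcore
from .simdata import CONDITIONS

D0_CAP = 1e6

#: contrast name → (numerator condition, denominator condition)
CONTRASTS = {
    "TNF_vs_control": ("TNF", "control"),
    "TNFsPD1_vs_control": ("TNF_sPD1", "control"),
    "TNFsPD1_vs_TNF": ("TNF_sPD1", "TNF"),
    "KO_PDL1_vs_TNF": ("KO_PDL1_TNF_sPD1", "TNF"),
    "KO_PDL2_vs_TNF": ("KO_PDL2_TNF_sPD1", "TNF"),
}


def build_design(
    design: pd.DataFrame, blocking: str = "random"
) -> tuple[pd.DataFrame, pd.Series | None]:
    """Design matrix with control as baseline; donor blocks or indicators.

    With one disease group: intercept (control mean) plus one indicator per
    non-control condition. With both groups: one control-mean column per
    group plus per-group condition indicators (a full interaction coding).
    ``blocking="random"`` returns donor labels for consensus-correlation
    estimation; ``blocking="fixed"`` appends donor indicator columns
    (dropping one donor per group).
    """
    if blocking not in ("random", "fixed"):
        raise ValueError("blocking must be 'random' or 'fixed'")
    counts = design["condition"].value_counts()
    lonely = counts[counts < 2]
    if len(lonely):
        raise ValueError(
            f"condition(s) with a single sample are not estimable: {list(lonely.index)}"
        )
    groups = list(dict.fromkeys(design["disease_group"]))
    cols: dict[str, np.ndarray] = {}
    for g in groups:
        in_g = (design["disease_group"] == g).to_numpy()
        name = f"{g}.control" if len(groups) > 1 else "control"
        cols[name] = in_g.astype(float)
        for c in CONDITIONS[1:]:
            if c not in set(design.loc[in_g, "condition"]):
                continue
            cname = f"{g}.{c}" if len(groups) > 1 else c
            cols[cname] = (in_g & (design["condition"] == c).to_numpy()).astype(float)
    x = pd.DataFrame(cols, index=design["sample_id"].to_numpy())
    blocks = pd.Series(
        design["donor_id"].to_numpy(), index=design["sample_id"].to_numpy()
    )
    if blocking == "fixed":
        for g in groups:
            donors = list(dict.fromkeys(design.loc[design["disease_group"] == g, "donor_id"]))
            for d in donors[1:]:
                x[f"donor.{d}"] = (design["donor_id"] == d).to_numpy().astype(float)
        return x, None
    return x, blocks


def consensus_correlation(
    y: pd.DataFrame | np.ndarray,
    design: pd.DataFrame | np.ndarray,
    blocks: pd.Series | np.ndarray,
    trim: float = 0.15,
    pooling: str = "components",
) -> float:
    """Pooled intra-block residual correlation across genes.

    Per gene, a moment estimator of the block (donor) and noise variance
    components from OLS residuals, corrected for the attenuation induced by
    the residual projection: with M = I − X(X'X)⁻¹X' and B the same-block
    indicator, the within-block residual cross-products and the residual sum
    of squares have expectations linear in (σ²_block, σ²_noise) with
    coefficients from tr/entries of MBM and M, giving an unbiased 2×2 solve
    per gene. The default pooling averages the variance components across
    genes and forms a single ratio σ²_block/(σ²_block+σ²_noise) — unbiased
    under the null and at planted correlations, because per-gene ratios are
    downward-skewed by the numerator/denominator coupling.
    ``pooling="atanh-trim"`` instead pools per-gene correlations by a
    two-sided 15%-trimmed mean on the atanh scale. The result is clamped to
    (−0.99, 0.99).
    """
    yv = np.asarray(y, dtype=float)
    x = np.asarray(design, dtype=float)
    b = np.asarray(blocks)
    uniq, inv = np.unique(b, return_inverse=True)
    sizes = np.bincount(inv)
    if np.sum(sizes >= 2) < 2:
        raise ValueError("need at least 2 blocks with at least 2 samples each")
    n, p = x.shape
    beta, *_ = np.linalg.lstsq(x, yv.T, rcond=None)
    resid = yv - (x @ beta).T

    h = x @ np.linalg.solve(x.T @ x, x.T)
    m = np.eye(n) - h
    bmat = (inv[:, None] == inv[None, :]).astype(float)
    mbm = m @ bmat @ m
    pair_mask = bmat.astype(bool) & ~np.eye(n, dtype=bool)
    a1 = mbm[pair_mask].sum() / 2.0
    a2 = m[pair_mask].sum() / 2.0
    b1 = np.trace(mbm)
    b2 = float(n - p)
    coef = np.array([[a1, a2], [b1, b2]])

    cross = np.einsum("gi,ij,gj->g", resid, np.triu(bmat - np.eye(n), 1), resid)
    ss = np.sum(resid**2, axis=1)
    sol = np.linalg.solve(coef, np.vstack([cross, ss]))
    sig_b, sig_e = sol[0], sol[1]
    if pooling == "components":
        mb, mt = float(np.mean(sig_b)), float(np.mean(sig_b + sig_e))
        pooled = mb / mt if mt > 0 else 0.0
    elif pooling == "atanh-trim":
        tot = sig_b + sig_e
        with np.errstate(invalid="ignore", divide="ignore"):
            rho_g = np.where(tot > 0, sig_b / tot, np.nan)
        rho_g = np.clip(rho_g[np.isfinite(rho_g)], -0.999, 0.999)
        pooled = float(np.tanh(stats.trim_mean(np.arctanh(rho_g), proportiontocut=trim)))
    else:
        raise ValueError("pooling must be 'components' or 'atanh-trim'")
    return float(np.clip(pooled, -0.99, 0.99))


@dataclass
class GLSFit:
    """Per-gene GLS estimates under block-exchangeable correlation."""

    coefficients: pd.DataFrame  # genes x coefficients
    stdev_unscaled: pd.DataFrame  # sqrt of diag of (X'V^-1X)^-1, genes x coef
    sigma2: np.ndarray  # residual variances
    df_resid: float
    cov_unscaled: np.ndarray  # genes x p x p
    coef_names: list[str]
    gene_ids: list[str]
    amean: np.ndarray  # average log2-CPM per gene
    rho: float


def _block_cholesky(blocks, rho: float, sample_order) -> np.ndarray:
    b = np.asarray(pd.Series(blocks).reindex(sample_order) if hasattr(blocks, "reindex") else blocks)
    n = len(b)
    c = np.eye(n)
    same = b[:, None] == b[None, :]
    c[same & ~np.eye(n, dtype=bool)] = rho
    try:
        L = np.linalg.cholesky(c)
    except np.linalg.LinAlgError as e:
        raise ValueError(f"block correlation rho={rho} is not positive definite") from e
    return L


def fit_gls(
    y: pd.DataFrame,
    weights: pd.DataFrame | None,
    design: pd.DataFrame | np.ndarray,
    blocks: pd.Series | None = None,
    rho: float = 0.0,
) -> GLSFit:
    """Gene-wise GLS with precision weights and intra-block correlation.

    The covariance for gene g is ``D_g C D_g`` with ``D_g = diag(1/sqrt(w_g))``
    and ``C = (1-rho) I + rho * (same-block indicator)``. With rho = 0 and
    unit weights this is ordinary least squares. Vectorized over genes via a
    shared Cholesky whitening of C.
    """
    x = np.asarray(design, dtype=float)
    coef_names = (
        list(design.columns) if isinstance(design, pd.DataFrame) else
        [f"x{i}" for i in range(x.shape[1])]
    )
    n, p = x.shape
    rank = np.linalg.matrix_rank(x)
    if rank < p:
        # name aliased columns via QR diagonal
        _, r = np.linalg.qr(x)
        bad = [coef_names[i] for i in range(p) if abs(r[i, i]) < 1e-10]
        raise ValueError(f"design matrix is rank deficient; aliased columns: {bad}")
    if n - p <= 0:
        raise ValueError("no residual degrees of freedom")
    yv = y.to_numpy(dtype=float)
    g = yv.shape[0]
    w = (
        np.ones_like(yv)
        if weights is None
        else weights.to_numpy(dtype=float)
    )
    if blocks is not None and rho != 0.0:
        L = _block_cholesky(blocks, rho, y.columns)
        linv = np.linalg.inv(L)
    else:
        linv = np.eye(n)
    sw = np.sqrt(w)  # genes x n
    xt = np.einsum("ij,gjk->gik", linv, sw[:, :, None] * x[None, :, :])
    yt = np.einsum("ij,gj->gi", linv, sw * yv)
    xtx = np.einsum("gij,gik->gjk", xt, xt)
    xty = np.einsum("gij,gi->gj", xt, yt)
    cov = np.linalg.inv(xtx)
    beta = np.einsum("gjk,gk->gj", cov, xty)
    resid = yt - np.einsum("gik,gk->gi", xt, beta)
    sigma2 = np.sum(resid**2, axis=1) / (n - p)
    sdu = np.sqrt(np.einsum("gjj->gj", cov))
    gene_ids = list(y.index)
    return GLSFit(
        coefficients=pd.DataFrame(beta, index=gene_ids, columns=coef_names),
        stdev_unscaled=pd.DataFrame(sdu, index=gene_ids, columns=coef_names),
        sigma2=sigma2,
        df_resid=float(n - p),
        cov_unscaled=cov,
        coef_names=coef_names,
        gene_ids=gene_ids,
        amean=yv.mean(axis=1),
        rho=rho,
    )


@dataclass
class EBayesState:
    """Empirical Bayes variance prior and per-gene posterior variances."""

    d0: float  # prior degrees of freedom (capped encoding of infinity)
    s0_sq: float  # prior variance
    s2_post: np.ndarray  # posterior (moderated) variances
    df_resid: float
    consensus_rho: float = 0.0

    def __post_init__(self):
        if self.s0_sq <= 0:
            raise ValueError("s0_sq must be positive")
        if self.d0 < 0:
            raise ValueError("d0 must be non-negative")


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def ebayes_moderate(
    s_g_sq: np.ndarray, d_g: float, rho: float = 0.0
) -> EBayesState:
    """Method-of-moments fit of the scaled inverse-chi-square variance prior.

    Matches the mean and excess variance of log residual variances to the
    digamma/trigamma moments of a log chi-square; the prior df d0 comes from
    inverting the trigamma function, with d0 = infinity encoded as 1e6 when
    the spread is at or below the chi-square floor.
    """
    s2 = np.asarray(s_g_sq, dtype=float)
    if len(s2) < 10:
        raise ValueError("empirical Bayes moment estimation needs >= 10 genes")
    if d_g <= 0:
        raise ValueError("residual df must be positive")
    ok = s2 > 0
    z = np.log(s2[ok])
    if np.var(z) < 1e-12:
        # degenerate: no spread at all; shrink completely to the common value
        s0_sq = float(np.exp(np.mean(z)))
        return EBayesState(
            d0=D0_CAP, s0_sq=s0_sq, s2_post=np.full_like(s2, s0_sq),
            df_resid=float(d_g), consensus_rho=rho,
        )
    e = z - special.digamma(d_g / 2.0) + np.log(d_g / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, d_g / 2.0))
    if evar > 0:
        d0 = min(2.0 * _trigamma_inverse(evar), D0_CAP)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = D0_CAP
        s0_sq = float(np.exp(emean))
    s2_post = (d0 * s0_sq + d_g * s2) / (d0 + d_g)
    return EBayesState(d0=d0, s0_sq=s0_sq, s2_post=s2_post, df_resid=float(d_g), consensus_rho=rho)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def contrast_test(
    fit: GLSFit,
    ebayes: EBayesState,
    contrast: np.ndarray | dict[str, float],
    contrast_name: str = "contrast",
) -> pd.DataFrame:
    """Moderated t-test of a contrast of coefficients → ContrastTable.

    Returns one row per gene: log2FC (the contrast estimate), moderated t,
    total df (residual + prior), raw and BH-adjusted two-sided p, and
    average expression.
    """
    if isinstance(contrast, dict):
        c = np.zeros(len(fit.coef_names))
        for k, v in contrast.items():
            if k not in fit.coef_names:
                raise ValueError(f"unknown coefficient {k!r}")
            c[fit.coef_names.index(k)] = v
    else:
        c = np.asarray(contrast, dtype=float)
    if len(c) != len(fit.coef_names):
        raise ValueError("contrast vector length must match the coefficient count")
    if np.all(c == 0):
        raise ValueError("contrast vector must be nonzero")
    est = fit.coefficients.to_numpy() @ c
    var_u = np.einsum("j,gjk,k->g", c, fit.cov_unscaled, c)
    se = np.sqrt(var_u * ebayes.s2_post)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, est / se, 0.0)
    df_total = min(ebayes.d0 + fit.df_resid, D0_CAP)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return pd.DataFrame(
        {
            "gene_id": fit.gene_ids,
            "contrast": contrast_name,
            "log2fc": est,
            "t": t,
            "df": df_total,
            "p": p,
            "p_adj": bh_adjust(p),
            "avg_expr": fit.amean,
        }
    ).set_index("gene_id")


def condition_contrast_vector(
    coef_names: list[str], numerator: str, denominator: str, group: str | None = None
) -> np.ndarray:
    """Contrast vector for condition A minus condition B in a coded design."""
    prefix = f"{group}." if group is not None and f"{group}.control" in coef_names else ""
    c = np.zeros(len(coef_names))

    def col(cond):
        return f"{prefix}{cond}"

    if numerator != "control":
        c[coef_names.index(col(numerator))] += 1.0
    if denominator != "control":
        c[coef_names.index(col(denominator))] -= 1.0
    if np.all(c == 0):
        raise ValueError("degenerate contrast (numerator equals denominator)")
    return c


@dataclass
class GroupResult:
    """Everything a per-group analysis produces, keyed for downstream ops."""

    group: str
    normalized: normcore.NormalizedMatrix
    fit: GLSFit
    ebayes: EBayesState
    tables: dict[str, pd.DataFrame]
    design: pd.DataFrame


def run_group_analysis(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    group: str | None = None,
    contrasts: tuple[str, ...] | None = None,
    min_count: int = 10,
    min_samples: int = 3,
    use_blocking: bool = True,
    genes: list[str] | None = None,
) -> GroupResult:
    """Full filter → TMM → voom → consensus correlation → GLS → eBayes chain.

    ``group`` restricts to one disease group (the study's primary mode:
    RA and NI are analysed separately, donor as a random effect).
    ``genes`` optionally restricts the universe before filtering (used by
    the bootstrap to stay on the originally kept genes).
    """
    if group is not None:
        keep = design["disease_group"] == group
        design = design.loc[keep].reset_index(drop=True)
        counts = counts[design["sample_id"].to_numpy()]
    if genes is not None:
        counts = counts.loc[[g for g in genes if g in counts.index]]
    x, blocks = build_design(design, blocking="random")
    norm = normcore.normalize(
        counts, design=x, min_count=min_count, min_samples=min_samples
    )
    rho = 0.0
    if use_blocking and blocks is not None:
        sizes = blocks.value_counts()
        if (sizes >= 2).sum() >= 2:
            rho = consensus_correlation(norm.log2_cpm, x, blocks.loc[norm.log2_cpm.columns])
    fit = fit_gls(norm.log2_cpm, norm.weights, x, blocks=blocks, rho=rho)
    eb = ebayes_moderate(fit.sigma2, fit.df_resid, rho=rho)
    if contrasts is None:
        present = set(design["condition"])
        contrasts = tuple(
            name
            for name, (num, den) in CONTRASTS.items()
            if {num, den} <= present
        )
    tables = {}
    for name in contrasts:
        num, den = CONTRASTS[name]
        c = condition_contrast_vector(fit.coef_names, num, den, group=group)
        tables[name] = contrast_test(fit, eb, c, contrast_name=name)
    return GroupResult(
        group=group or "all", normalized=norm, fit=fit, ebayes=eb,
        tables=tables, design=design,
    )


class DonorBlockedLM:
    """sklearn-style estimator for the donor-blocked moderated linear model.

    ``fit(X, design)`` with X samples x genes (log2-CPM) learns coefficients,
    the consensus intra-donor correlation and the variance prior; fitted
    attributes carry trailing underscores. ``contrast`` returns a moderated-t
    ContrastTable.
    """

    def __init__(self, use_blocking: bool = True):
        self.use_blocking = use_blocking

    def get_params(self, deep: bool = True) -> dict:
        return {"use_blocking": self.use_blocking}

    def set_params(self, **params) -> "DonorBlockedLM":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: pd.DataFrame, design: pd.DataFrame, weights: pd.DataFrame | None = None):
        y = X.T  # genes x samples
        xmat, blocks = build_design(design, blocking="random")
        rho = 0.0
        if self.use_blocking and (blocks.value_counts() >= 2).sum() >= 2:
            rho = consensus_correlation(y, xmat, blocks.loc[y.columns])
        w = None if weights is None else weights.T
        self.fit_ = fit_gls(y, w, xmat, blocks=blocks, rho=rho)
        self.ebayes_ = ebayes_moderate(self.fit_.sigma2, self.fit_.df_resid, rho=rho)
        self.consensus_rho_ = rho
        self.coef_ = self.fit_.coefficients
        return self

    def contrast(self, contrast, name: str = "contrast") -> pd.DataFrame:
        if not hasattr(self, "fit_"):
            raise RuntimeError("DonorBlockedLM must be fitted before calling contrast")
        return contrast_test(self.fit_, self.ebayes_, contrast, contrast_name=name)
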