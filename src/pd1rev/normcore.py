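"""Expression filtering, TMM normalization, log2-CPM and precision weights.

The normalization chain for bulk counts: CPM-threshold filtering keyed to the
smallest library, trimmed-mean-of-M-values (TMM) scaling factors, log2-CPM
transformation with a prior count, and mean-variance precision weights from a
lowess trend of residual standard deviations (the voom recipe).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _lowess

WEIGHT_BOUNDS = (1e-6, 1e6)


@dataclass
class NormalizedMatrix:
    """log2-CPM values, TMM factors and precision weights for kept genes."""

    log2_cpm: pd.DataFrame  # genes x samples
    norm_factors: pd.Series  # per sample, geometric mean 1
    weights: pd.DataFrame  # genes x samples, positive finite
    kept_genes: list[str]

    def __post_init__(self):
        gm = np.exp(np.mean(np.log(self.norm_factors.to_numpy())))
        if abs(gm - 1.0) > 1e-8:
            raise ValueError("norm_factors must have geometric mean 1")
        w = self.weights.to_numpy()
        if not (np.all(np.isfinite(w)) and np.all(w > 0)):
            raise ValueError("weights must be strictly positive and finite")


def _library_sizes(counts: pd.DataFrame) -> pd.Series:
    lib = counts.sum(axis=0)
    zero = lib[lib == 0]
    if len(zero):
        raise ValueError(f"all-zero library for sample(s): {list(zero.index)}")
    return lib


def cpm_filter(
    counts: pd.DataFrame, min_count: int = 10, min_samples: int = 3
) -> list[str]:
    """Keep genes exceeding the CPM threshold set by the smallest library.

    The threshold is ``min_count * 1e6 / min(library sizes)`` — the CPM
    value corresponding to ``min_count`` reads in the smallest library — and
    a gene is kept iff its CPM reaches it in at least ``min_samples``
    samples. Returns kept gene ids in input order.
    """
    if min_count < 1 or min_samples < 1:
        raise ValueError("min_count and min_samples must be >= 1")
    lib = _library_sizes(counts)
    threshold = min_count * 1e6 / lib.min()
    cpm = counts * 1e6 / lib
    keep = (cpm >= threshold).sum(axis=1) >= min_samples
    return list(counts.index[keep])


def tmm_factors(
    counts: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05
) -> pd.Series:
    """Trimmed mean of M-values scaling factors, geometric mean 1.

    The reference sample is the one whose 75th-percentile count fraction is
    closest to the mean across samples. For each sample, genes with a zero
    count in either member of the pair are excluded; log-ratios (M) and
    average log abundances (A) are doubly trimmed (two-sided ``trim_m`` on M
    by rank, ``trim_a`` on A by rank) and the factor is 2 to the
    precision-weighted mean of the surviving M-values, with weights from the
    delta-method binomial variance.
    """
    if not (0 <= trim_m < 0.5 and 0 <= trim_a < 0.5):
        raise ValueError("trim fractions must lie in [0, 0.5)")
    if counts.shape[1] < 2:
        raise ValueError("TMM requires at least 2 samples")
    y = counts.to_numpy(dtype=float)
    lib = _library_sizes(counts).to_numpy(dtype=float)
    frac = y / lib
    q75 = np.quantile(frac, 0.75, axis=0)
    ref = int(np.argmin(np.abs(q75 - q75.mean())))

    factors = np.ones(counts.shape[1])
    for k in range(counts.shape[1]):
        if k == ref:
            continue
        factors[k] = _tmm_pair(y[:, k], y[:, ref], lib[k], lib[ref], trim_m, trim_a)
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="norm_factor")


def _tmm_pair(yk, yr, nk, nr, trim_m, trim_a) -> float:
    ok = (yk > 0) & (yr > 0)
    if ok.sum() < 2:
        warnings.warn("fewer than 2 genes usable for TMM pair; factor set to 1")
        return 1.0
    yk, yr = yk[ok], yr[ok]
    m = np.log2((yk / nk) / (yr / nr))
    a = 0.5 * np.log2((yk / nk) * (yr / nr))
    w = (nk - yk) / (nk * yk) + (nr - yr) / (nr * yr)
    n = len(m)
    lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if keep.sum() == 0 or w[keep].sum() == 0:
        warnings.warn("TMM trimming removed all genes; factor set to 1")
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def log2_cpm(
    counts: pd.DataFrame,
    norm_factors: pd.Series | None = None,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """log2 counts-per-million against TMM-effective library sizes.

    ``log2((count + prior) / (lib * factor + 2 * prior) * 1e6)``; the doubled
    prior in the denominator keeps the transform consistent with downstream
    mean-variance weighting.
    """
    if prior_count < 0:
        raise ValueError("prior_count must be non-negative")
    lib = _library_sizes(counts)
    if norm_factors is None:
        norm_factors = pd.Series(1.0, index=counts.columns)
    eff = lib * norm_factors.reindex(counts.columns)
    if (eff <= 0).any():
        raise ValueError("norm_factors must be positive")
    return np.log2((counts + prior_count) / (eff + 2 * prior_count) * 1e6)


def voom_weights(
    log2cpm: pd.DataFrame,
    counts: pd.DataFrame,
    design: np.ndarray | pd.DataFrame,
    lowess_span: float = 0.5,
) -> pd.DataFrame:
    """Mean-variance precision weights (inverse fourth power of trend sd).

    Per gene, ordinary least squares on the design gives residual standard
    deviations; their square roots are lowess-smoothed against average log
    count, the trend is evaluated at each observation's fitted log count,
    and the weight is the predicted standard deviation to the power −4,
    clamped to a positive finite range.
    """
    x = np.asarray(design, dtype=float)
    n, p = x.shape
    if n - p <= 0:
        raise ValueError("residual degrees of freedom must be positive")
    if np.linalg.matrix_rank(x) < p:
        raise ValueError("design matrix is not of full column rank")
    y = log2cpm.to_numpy(dtype=float)
    lib = counts.sum(axis=0).to_numpy(dtype=float)

    beta, *_ = np.linalg.lstsq(x, y.T, rcond=None)
    fitted = (x @ beta).T  # genes x samples
    resid = y - fitted
    sigma = np.sqrt(np.sum(resid**2, axis=1) / (n - p))
    sqrt_sd = np.sqrt(sigma)
    # average and fitted log2 counts (shift log2-CPM back to the count scale)
    shift = np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    sx = y.mean(axis=1) + shift
    fitted_logcount = fitted + (np.log2(lib + 1.0) - np.log2(1e6))

    trend = _lowess(sqrt_sd, sx, frac=lowess_span, return_sorted=True)
    tx, ty = trend[:, 0], trend[:, 1]
    pred_sqrt_sd = np.interp(fitted_logcount, tx, ty)  # constant beyond range
    w = np.clip(pred_sqrt_sd, 1e-12, None) ** -4
    w = np.clip(w, *WEIGHT_BOUNDS)
    return pd.DataFrame(w, index=log2cpm.index, columns=log2cpm.columns)


def normalize(
    counts: pd.DataFrame,
    design: np.ndarray | pd.DataFrame | None = None,
    min_count: int = 10,
    min_samples: int = 3,
    prior_count: float = 0.5,
    lowess_span: float = 0.5,
) -> NormalizedMatrix:
    """Filter → TMM → log2-CPM → precision weights in one call.

    With no design matrix, weights are computed against an intercept-only
    model (pure mean-variance trend).
    """
    kept = cpm_filter(counts, min_count=min_count, min_samples=min_samples)
    sub = counts.loc[kept]
    factors = tmm_factors(sub)
    lc = log2_cpm(sub, factors, prior_count=prior_count)
    if design is None:
        design = np.ones((counts.shape[1], 1))
    w = voom_weights(lc, sub, design, lowess_span=lowess_span)
    return NormalizedMatrix(log2_cpm=lc, norm_factors=factors, weights=w, kept_genes=kept)


class TMMNormalizer:
    """sklearn-style transformer: counts (samples x genes) → log2-CPM.

    ``fit`` learns the kept-gene set and TMM factors; ``transform`` returns
    the log2-CPM of the kept genes. Follows the scikit-learn estimator
    contract (get_params/set_params, trailing-underscore fitted attributes).
    """

    def __init__(self, min_count: int = 10, min_samples: int = 3, prior_count: float = 0.5):
        self.min_count = min_count
        self.min_samples = min_samples
        self.prior_count = prior_count

    def get_params(self, deep: bool = True) -> dict:
        return {
            "min_count": self.min_count,
            "min_samples": self.min_samples,
            "prior_count": self.prior_count,
        }

    def set_params(self, **params) -> "TMMNormalizer":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: pd.DataFrame, y=None) -> "TMMNormalizer":
        counts = self._as_genes_by_samples(X)
        self.kept_genes_ = cpm_filter(counts, self.min_count, self.min_samples)
        self.norm_factors_ = tmm_factors(counts.loc[self.kept_genes_])
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        counts = self._as_genes_by_samples(X)
        lc = log2_cpm(
            counts.loc[self.kept_genes_], self.norm_factors_, self.prior_count
        )
        return lc.T

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)

    @staticmethod
    def _as_genes_by_samples(X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise TypeError("TMMNormalizer expects a samples x genes DataFrame")
        return X.T
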