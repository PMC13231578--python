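"""PCA overviews, residual PCA after cell-line correction, bootstrap stability.

The bootstrap resamples donors (cell lines) with replacement within a disease
group, refits the whole filtering-through-contrast chain, and scores the
Spearman correlation of replicate log2FCs against the original estimates:
median > 0.9 indicates stable gene-level rankings, < 0.8 strong dependence
on individual samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA as _PCA

from . import dex

STABLE_CUT = 0.9
UNSTABLE_CUT = 0.8


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # genes x components
    variance_explained: np.ndarray


def pca(
    matrix: pd.DataFrame, center: bool = True, scale: bool = False
) -> PCAResult:
    """PCA of samples (columns are samples, rows genes/features).

    Components are ordered by decreasing variance and the explained-variance
    ratios sum to 1.
    """
    if matrix.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    x = matrix.to_numpy(dtype=float).T  # samples x genes
    if center:
        x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("cannot scale: zero-variance feature present")
        x = x / sd
    if np.allclose(x, 0):
        raise ValueError("constant matrix has no principal components")
    model = _PCA(n_components=None, svd_solver="full")
    scores = model.fit_transform(x)
    k = scores.shape[1]
    comp = [f"PC{i+1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.columns, columns=comp),
        loadings=pd.DataFrame(model.components_.T, index=matrix.index, columns=comp),
        variance_explained=model.explained_variance_ratio_,
    )


def residual_pca(y: pd.DataFrame, design: pd.DataFrame) -> PCAResult:
    """PCA of residuals after removing per-gene donor (cell line) means.

    The donor fixed-effect fit is a projection: within every donor, each
    gene's residuals sum to zero, so the result shows the variance not
    captured by cell line.
    """
    donors = design.set_index("sample_id")["donor_id"].reindex(y.columns)
    sizes = donors.value_counts()
    single = sizes[sizes < 2]
    if len(single):
        raise ValueError(f"singleton donor(s) cannot be residualised: {list(single.index)}")
    resid = y.copy()
    for d, cols in donors.groupby(donors).groups.items():
        resid[list(cols)] = y[list(cols)].sub(y[list(cols)].mean(axis=1), axis=0)
    return pca(resid, center=True, scale=False)


@dataclass
class BootstrapStability:
    """Replicate-level Spearman correlations of log2FC rankings."""

    contrast_name: str
    rhos: np.ndarray
    n_replicates: int
    seed: int
    n_redrawn: int = 0
    donor_multisets: list[tuple[str, ...]] = field(default_factory=list)

    @property
    def median_rho(self) -> float:
        return float(np.median(self.rhos))

    @property
    def category(self) -> str:
        m = self.median_rho
        if m > STABLE_CUT:
            return "stable"
        if m < UNSTABLE_CUT:
            return "unstable"
        return "intermediate"


def _resample_counts(
    counts: pd.DataFrame, design: pd.DataFrame, drawn_donors: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Materialise a donor resample; duplicated donors become pseudo-donors."""
    frames, rows = [], []
    for k, donor in enumerate(drawn_donors):
        sub = design[design["donor_id"] == donor]
        pseudo = f"{donor}#bs{k}"
        for r in sub.itertuples(index=False):
            new_id = f"{r.sample_id}#bs{k}"
            rows.append(
                {
                    "sample_id": new_id,
                    "donor_id": pseudo,
                    "disease_group": r.disease_group,
                    "condition": r.condition,
                }
            )
            frames.append(counts[r.sample_id].rename(new_id))
    return pd.concat(frames, axis=1), pd.DataFrame(rows)


def bootstrap_stability(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    contrast_name: str,
    n_replicates: int = 1000,
    seed: int = 0,
    group: str | None = None,
    min_count: int = 10,
    min_samples: int = 3,
    allow_identical_donors: bool = True,
    max_redraws: int = 1000,
) -> BootstrapStability:
    """Stability of a contrast's log2FC ranking under donor resampling.

    Donors are resampled with replacement within the group, every sample of
    a drawn donor is carried along (duplicates relabelled as distinct
    pseudo-donors so the model stays estimable), the full
    filtering-through-contrast pipeline is rerun restricted to the
    originally kept genes, and the replicate log2FCs are compared to the
    original by Spearman correlation over shared genes.
    """
    if n_replicates < 50:
        raise ValueError("n_replicates must be >= 50")
    if group is not None:
        design = design.loc[design["disease_group"] == group].reset_index(drop=True)
        counts = counts[design["sample_id"].to_numpy()]
    donors = sorted(set(design["donor_id"]))
    if len(donors) < 2:
        raise ValueError("bootstrap needs at least 2 donors in the group")
    original = dex.run_group_analysis(
        counts, design, contrasts=(contrast_name,),
        min_count=min_count, min_samples=min_samples,
    )
    ref = original.tables[contrast_name]["log2fc"]
    kept = list(ref.index)
    needed = set()
    num, den = dex.CONTRASTS[contrast_name]
    needed = {num, den} if den != "control" else {num, "control"}

    rng = np.random.default_rng(seed)
    rhos, multisets = [], []
    n_redrawn = 0
    for _ in range(n_replicates):
        for _attempt in range(max_redraws):
            drawn = list(rng.choice(donors, size=len(donors), replace=True))
            if not allow_identical_donors and len(set(drawn)) == 1:
                n_redrawn += 1
                continue
            bs_counts, bs_design = _resample_counts(counts, design, drawn)
            if not needed <= set(bs_design["condition"]):
                n_redrawn += 1
                continue
            break
        else:
            raise RuntimeError("could not draw a valid bootstrap resample")
        res = dex.run_group_analysis(
            bs_counts, bs_design, contrasts=(contrast_name,),
            min_count=min_count, min_samples=min_samples, genes=kept,
        )
        boot = res.tables[contrast_name]["log2fc"]
        shared = ref.index.intersection(boot.index)
        rho = stats.spearmanr(ref.loc[shared], boot.loc[shared]).statistic
        rhos.append(rho)
        multisets.append(tuple(sorted(drawn)))
    return BootstrapStability(
        contrast_name=contrast_name,
        rhos=np.asarray(rhos),
        n_replicates=n_replicates,
        seed=seed,
        n_redrawn=n_redrawn,
        donor_multisets=multisets,
    )


def enumerate_donor_multisets(donors: list[str]) -> dict[tuple[str, ...], float]:
    """Exact multiset probabilities over all ordered with-replacement draws."""
    from itertools import product

    counts: dict[tuple[str, ...], int] = {}
    total = 0
    for drawn in product(donors, repeat=len(donors)):
        key = tuple(sorted(drawn))
        counts[key] = counts.get(key, 0) + 1
        total += 1
    return {k: v / total for k, v in counts.items()}
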