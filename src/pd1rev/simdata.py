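"""Synthetic data generators with recorded ground truth.

Emulates the five-condition FLS stimulation study: bulk RNA-seq counts with
donor random effects and planted sPD1-responsive genes whose response depends
on PD-L1, PD-L2 or both; matching qPCR Ct tables; and single-cell matrices
with per-sample / per-cell-type structure. Every generator is a deterministic
function of its seed and records the planted truth for recovery tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = (
    "control",
    "TNF",
    "TNF_sPD1",
    "KO_PDL1_TNF_sPD1",
    "KO_PDL2_TNF_sPD1",
)
GROUPS = ("NI", "RA")
LIGAND_LABELS = ("none", "PD-L1", "PD-L2", "both")

#: conditions carrying the TNF stimulus
_TNF_CONDITIONS = frozenset(CONDITIONS[1:])
#: conditions carrying sPD1 treatment
_SPD1_CONDITIONS = frozenset(CONDITIONS[2:])


def make_design(
    n_donors_per_group: int = 3,
    groups: tuple[str, ...] = GROUPS,
    conditions: tuple[str, ...] = CONDITIONS,
) -> pd.DataFrame:
    """Balanced sample sheet: every donor measured under every condition.

    Mirrors the study layout of three RA and three non-inflammatory (NI)
    donors, five conditions each.
    """
    rows = []
    for g in groups:
        for d in range(1, n_donors_per_group + 1):
            donor = f"{g}_donor{d}"
            for c in conditions:
                rows.append(
                    {
                        "sample_id": f"{donor}.{c}",
                        "donor_id": donor,
                        "disease_group": g,
                        "condition": c,
                    }
                )
    return pd.DataFrame(rows)


def validate_design(design: pd.DataFrame) -> list[str]:
    """Check SampleDesign invariants; returns a list of violation messages."""
    problems = []
    required = {"sample_id", "donor_id", "disease_group", "condition"}
    missing = required - set(design.columns)
    if missing:
        return [f"design missing columns: {sorted(missing)}"]
    dup = design["sample_id"][design["sample_id"].duplicated()]
    if len(dup):
        problems.append(f"duplicate sample_id: {sorted(set(dup))}")
    bad_cond = set(design["condition"]) - set(CONDITIONS)
    if bad_cond:
        problems.append(f"unknown condition label(s): {sorted(bad_cond)}")
    per_donor = design.groupby("donor_id")
    for donor, sub in per_donor:
        if sub["disease_group"].nunique() > 1:
            problems.append(f"donor {donor} appears in more than one disease group")
        counts = sub["condition"].value_counts()
        if (counts > 1).any():
            problems.append(f"donor {donor} has repeated condition(s)")
    return problems


@dataclass
class SyntheticTruth:
    """Planted generative parameters for one synthetic study.

    Expression for gene *g* in sample *s* is negative binomial with
    ``mu = L_s * 2**(baseline_g + donor_g + condition_g) / C`` where ``C``
    normalises baseline abundances, and variance ``mu + phi * mu**2``.
    """

    gene_ids: list[str]
    baseline_log2_mean: np.ndarray
    dispersion: np.ndarray
    donor_effects: pd.DataFrame  # genes x donors, additive log2 shifts
    tnf_log2fc: pd.DataFrame  # genes x groups
    spd1_log2fc: pd.DataFrame  # genes x groups
    ligand_dependency: np.ndarray  # per gene, one of LIGAND_LABELS
    library_sizes: pd.Series  # per sample intended depth
    seed: int
    responsive_genes: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        if np.any(self.dispersion <= 0):
            raise ValueError("dispersion must be strictly positive")
        if np.any(self.library_sizes <= 0):
            raise ValueError("library_sizes must be strictly positive")
        bad = set(np.unique(self.ligand_dependency)) - set(LIGAND_LABELS)
        if bad:
            raise ValueError(f"unknown ligand_dependency labels: {sorted(bad)}")
        dep = self.ligand_dependency != "none"
        has_effect = (np.abs(self.spd1_log2fc.to_numpy()) > 0).any(axis=1)
        if np.any(dep & ~has_effect):
            raise ValueError(
                "genes with ligand_dependency != none must carry a nonzero sPD1 effect"
            )

    def planted_responsive(self, group: str) -> list[str]:
        """Gene ids planted as ligand-dependent sPD1 responders in a group."""
        mask = (self.ligand_dependency != "none") & (
            np.abs(self.spd1_log2fc[group].to_numpy()) > 0
        )
        return [g for g, m in zip(self.gene_ids, mask) if m]

    def log2_signal(self, donor_id: str, group: str, condition: str) -> np.ndarray:
        """Per-gene log2 expression signal for one sample (no noise)."""
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition label: {condition!r}")
        if donor_id not in self.donor_effects.columns:
            raise ValueError(f"donor {donor_id!r} missing from truth")
        eta = self.baseline_log2_mean + self.donor_effects[donor_id].to_numpy()
        if condition in _TNF_CONDITIONS:
            eta = eta + self.tnf_log2fc[group].to_numpy()
        if condition in _SPD1_CONDITIONS:
            eta = eta + self.spd1_log2fc[group].to_numpy() * self._spd1_share(condition)
        return eta

    def _spd1_share(self, condition: str) -> np.ndarray:
        """Fraction of the planted sPD1 effect surviving in a condition.

        Knocking out a ligand removes that ligand's share of the effect:
        all of it for a matched single-ligand gene, half for a "both" gene
        (additive 50/50 split), none for the other ligand or for
        ligand-independent genes.
        """
        share = np.ones(len(self.gene_ids))
        if condition == "KO_PDL1_TNF_sPD1":
            share[self.ligand_dependency == "PD-L1"] = 0.0
            share[self.ligand_dependency == "both"] = 0.5
        elif condition == "KO_PDL2_TNF_sPD1":
            share[self.ligand_dependency == "PD-L2"] = 0.0
            share[self.ligand_dependency == "both"] = 0.5
        return share


def make_truth(
    design: pd.DataFrame,
    n_genes: int = 2000,
    seed: int = 0,
    *,
    frac_tnf_de: float = 0.15,
    tnf_lfc_scale: float = 1.5,
    tnf_lfc_dist: str = "fixed",
    n_responsive: int = 0,
    spd1_lfc: float = 1.5,
    responsive_in: tuple[str, ...] = GROUPS,
    dampen_group: str | None = None,
    dampen_frac: float = 0.2,
    dampen_delta: float = -1.0,
    sigma_donor: float = 0.3,
    phi_median: float = 0.05,
    phi_sigma: float = 0.4,
    mean_library_size: float = 30e6,
    lib_sigma: float = 0.2,
    baseline_mean: float = 4.0,
    baseline_sd: float = 1.5,
) -> SyntheticTruth:
    """Draw a SyntheticTruth for a given design.

    Defaults mirror the study scale where stated (~30M reads per sample,
    3 donors per group, five conditions); effect sizes and variance
    components are free parameters of the generator. TNF-responsive genes
    get log2FCs of magnitude ``tnf_lfc_scale`` with balanced alternating
    signs (``tnf_lfc_dist="fixed"``) or drawn Normal(0, tnf_lfc_scale)
    (``tnf_lfc_dist="normal"``, a pervasive heterogeneous response);
    ``n_responsive`` genes get a ligand-dependent sPD1 effect of magnitude
    ``spd1_lfc`` (dependencies cycling PD-L1 / PD-L2 / both, alternating
    sign) in the groups listed in ``responsive_in``. ``dampen_group`` plants
    an additional ligand-independent sPD1 shift of ``dampen_delta`` on a
    fraction ``dampen_frac`` of the TNF-responsive genes in that group only
    (the dampening scenario).
    """
    problems = validate_design(design)
    if problems:
        raise ValueError("invalid design: " + "; ".join(problems))
    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    baseline = rng.normal(baseline_mean, baseline_sd, n_genes)
    dispersion = np.exp(rng.normal(np.log(phi_median), phi_sigma, n_genes))
    donors = list(dict.fromkeys(design["donor_id"]))
    donor_eff = pd.DataFrame(
        rng.normal(0.0, sigma_donor, (n_genes, len(donors))),
        index=gene_ids,
        columns=donors,
    )
    groups = list(dict.fromkeys(design["disease_group"]))
    tnf = pd.DataFrame(0.0, index=gene_ids, columns=groups)
    spd1 = pd.DataFrame(0.0, index=gene_ids, columns=groups)
    dependency = np.array(["none"] * n_genes, dtype=object)

    n_tnf = int(round(frac_tnf_de * n_genes))
    perm = rng.permutation(n_genes)
    tnf_idx = perm[:n_tnf]
    resp_idx = perm[n_tnf : n_tnf + n_responsive]
    if n_tnf:
        if tnf_lfc_dist == "fixed":
            effects = tnf_lfc_scale * np.where(np.arange(n_tnf) % 2 == 0, 1.0, -1.0)
        elif tnf_lfc_dist == "normal":
            effects = rng.normal(0.0, tnf_lfc_scale, n_tnf)
        else:
            raise ValueError("tnf_lfc_dist must be 'fixed' or 'normal'")
        for g in groups:
            tnf.iloc[tnf_idx, tnf.columns.get_loc(g)] = effects
    for k, i in enumerate(resp_idx):
        dependency[i] = ("PD-L1", "PD-L2", "both")[k % 3]
        sign = 1.0 if k % 2 == 0 else -1.0
        for g in responsive_in:
            if g in spd1.columns:
                spd1.iloc[i, spd1.columns.get_loc(g)] = sign * spd1_lfc
    if dampen_group is not None:
        if dampen_group not in groups:
            raise ValueError(f"dampen_group {dampen_group!r} not in design groups")
        n_damp = int(round(dampen_frac * n_tnf))
        up_idx = [i for i in tnf_idx if tnf.iloc[i][dampen_group] > 0][:n_damp]
        spd1.iloc[up_idx, spd1.columns.get_loc(dampen_group)] += dampen_delta

    lib = pd.Series(
        np.exp(rng.normal(np.log(mean_library_size), lib_sigma, len(design))),
        index=design["sample_id"].to_numpy(),
        name="library_size",
    )
    return SyntheticTruth(
        gene_ids=gene_ids,
        baseline_log2_mean=baseline,
        dispersion=dispersion,
        donor_effects=donor_eff,
        tnf_log2fc=tnf,
        spd1_log2fc=spd1,
        ligand_dependency=dependency,
        library_sizes=lib,
        seed=seed,
        responsive_genes={
            g: [gene_ids[i] for i in resp_idx] for g in responsive_in
        },
    )


def expected_counts(truth: SyntheticTruth, design: pd.DataFrame) -> pd.DataFrame:
    """NB means mu for every gene x sample (the noiseless signal)."""
    unknown = set(design["condition"]) - set(CONDITIONS)
    if unknown:
        raise ValueError(f"unknown condition label: {sorted(unknown)[0]!r}")
    missing = set(design["donor_id"]) - set(truth.donor_effects.columns)
    if missing:
        raise ValueError(f"donor {sorted(missing)[0]!r} missing from truth")
    missing_lib = set(design["sample_id"]) - set(truth.library_sizes.index)
    if missing_lib:
        raise ValueError(
            f"sample {sorted(missing_lib)[0]!r} has no library size in truth"
        )
    norm = np.sum(2.0 ** truth.baseline_log2_mean)
    cols = {}
    for row in design.itertuples(index=False):
        eta = truth.log2_signal(row.donor_id, row.disease_group, row.condition)
        cols[row.sample_id] = truth.library_sizes[row.sample_id] * 2.0**eta / norm
    return pd.DataFrame(cols, index=truth.gene_ids)


def simulate_bulk_counts(
    truth: SyntheticTruth, design: pd.DataFrame, seed: int | None = None
) -> pd.DataFrame:
    """Draw a gene x sample NB count matrix from the planted truth.

    ``counts ~ NB(mu, phi)`` with ``var = mu + phi mu^2``; the mean is the
    library-size-scaled exponentiated sum of baseline, donor and active
    condition effects. Knockout conditions suppress the sPD1 effect share
    of the matching ligand. Deterministic given the seed (defaults to
    ``truth.seed``).
    """
    mu = expected_counts(truth, design).to_numpy()
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    size = 1.0 / truth.dispersion  # NB shape; var = mu + mu^2/size
    p = size[:, None] / (size[:, None] + mu)
    counts = rng.negative_binomial(size[:, None], p)
    return pd.DataFrame(
        counts, index=truth.gene_ids, columns=design["sample_id"].to_numpy()
    )


def simulate_qpcr(
    truth: SyntheticTruth,
    design: pd.DataFrame,
    targets: list[str],
    reference_gene: str,
    noise_sd: float = 0.2,
    seed: int | None = None,
    ct_anchor: float = 24.0,
    n_replicates: int = 2,
) -> pd.DataFrame:
    """Simulate a Ct table (technical duplicates) consistent with the truth.

    Ct decreases one unit per doubling of expression:
    ``Ct = ct_anchor - (log2 signal - mean baseline) + N(0, noise_sd)``.
    At ``noise_sd = 0`` the comparative-Ct log2FC equals the planted effect
    exactly. The reference gene must be free of condition effects (the
    normalisation assumption of the ΔΔCt method).
    """
    gi = {g: k for k, g in enumerate(truth.gene_ids)}
    for g in list(targets) + [reference_gene]:
        if g not in gi:
            raise ValueError(f"gene {g!r} not in truth")
    r = gi[reference_gene]
    ref_effects = np.concatenate(
        [truth.tnf_log2fc.iloc[r].to_numpy(), truth.spd1_log2fc.iloc[r].to_numpy()]
    )
    if np.any(ref_effects != 0):
        raise ValueError(
            f"reference gene {reference_gene!r} carries a planted condition effect; "
            "it cannot be used for ΔΔCt normalization"
        )
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    center = float(np.mean(truth.baseline_log2_mean))
    rows = []
    genes = list(dict.fromkeys(list(targets) + [reference_gene]))
    for row in design.itertuples(index=False):
        eta = truth.log2_signal(row.donor_id, row.disease_group, row.condition)
        for g in genes:
            ct0 = ct_anchor - (eta[gi[g]] - center)
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "sample_id": row.sample_id,
                        "condition": row.condition,
                        "target": g,
                        "replicate": rep,
                        "ct": ct0 + rng.normal(0.0, noise_sd) if noise_sd > 0 else ct0,
                    }
                )
    return pd.DataFrame(rows)


def simulate_single_cells(
    n_samples: int = 10,
    cells_per_sample: int = 200,
    cell_types: tuple[str, ...] = ("fibroblast", "tcell", "monocyte"),
    richness_labels: list[str] | None = None,
    marker_effects: dict[str, list[tuple[str, str, float]]] | None = None,
    seed: int = 0,
    *,
    n_genes: int = 2000,
    n_mito: int = 50,
    mito_share: float = 0.05,
    mean_depth: float = 6000.0,
    depth_sigma: float = 0.25,
    low_quality_fraction: float = 0.0,
    low_depth: float = 150.0,
    high_mito_share: float = 0.6,
):
    """Sparse single-cell counts with planted structure, as an AnnData.

    Each cell draws a lognormal depth and multinomial counts over a gene
    abundance profile; ``n_mito`` genes carry the ``MT-`` prefix and a
    baseline ``mito_share`` of reads. ``marker_effects`` maps a gene id to
    ``(kind, level, log2fc)`` triples with kind in {"cell_type",
    "richness"}; the gene's abundance is shifted by ``2**log2fc`` in cells
    of that type / samples of that richness. A ``low_quality_fraction`` of
    cells is planted to fail QC: half by collapsed depth, half by an
    inflated mitochondrial share.
    """
    import anndata as ad
    from scipy import sparse

    if cells_per_sample < 1:
        raise ValueError("cells_per_sample must be >= 1")
    if not cell_types:
        raise ValueError("cell_types must be non-empty")
    if richness_labels is None:
        richness_labels = [
            "lymphocyte-rich" if i < n_samples // 2 else "lymphocyte-poor"
            for i in range(n_samples)
        ]
    if len(richness_labels) != n_samples:
        raise ValueError("richness_labels must have one entry per sample")
    bad = set(richness_labels) - {"lymphocyte-rich", "lymphocyte-poor"}
    if bad:
        raise ValueError(f"unknown richness label(s): {sorted(bad)}")
    marker_effects = marker_effects or {}

    rng = np.random.default_rng(seed)
    gene_ids = [f"MT-G{i:03d}" for i in range(n_mito)] + [
        f"SC{i:05d}" for i in range(n_genes - n_mito)
    ]
    gidx = {g: k for k, g in enumerate(gene_ids)}
    for g in marker_effects:
        if g not in gidx:
            raise ValueError(f"marker gene {g!r} not among generated genes")
    base = np.exp(rng.normal(0.0, 1.0, n_genes))
    is_mito = np.array([g.startswith("MT-") for g in gene_ids])
    # fix the mitochondrial read share at mito_share
    base[is_mito] *= (mito_share / (1 - mito_share)) * base[~is_mito].sum() / base[
        is_mito
    ].sum()

    sample_ids = [f"S{i:02d}" for i in range(n_samples)]
    rows, obs_rows = [], []
    for si, sid in enumerate(sample_ids):
        richness = richness_labels[si]
        types = rng.choice(cell_types, size=cells_per_sample)
        lowq = rng.random(cells_per_sample) < low_quality_fraction
        lowq_kind = rng.integers(0, 2, cells_per_sample)  # 0 depth, 1 mito
        for ci in range(cells_per_sample):
            ct = types[ci]
            alpha = base.copy()
            for g, effs in marker_effects.items():
                for kind, level, lfc in effs:
                    if (kind == "cell_type" and level == ct) or (
                        kind == "richness" and level == richness
                    ):
                        alpha[gidx[g]] *= 2.0**lfc
            if lowq[ci] and lowq_kind[ci] == 1:
                tot_m, tot_o = alpha[is_mito].sum(), alpha[~is_mito].sum()
                alpha[is_mito] *= (high_mito_share / (1 - high_mito_share)) * tot_o / tot_m
            depth = float(np.exp(rng.normal(np.log(mean_depth), depth_sigma)))
            if lowq[ci] and lowq_kind[ci] == 0:
                depth = low_depth
            counts = rng.multinomial(int(round(depth)), alpha / alpha.sum())
            rows.append(counts)
            obs_rows.append(
                {
                    "cell_id": f"{sid}.c{ci:04d}",
                    "sample_id": sid,
                    "cell_type": ct,
                    "richness": richness,
                    "planted_low_quality": bool(lowq[ci]),
                }
            )
    x = sparse.csr_matrix(np.asarray(rows))
    obs = pd.DataFrame(obs_rows).set_index("cell_id")
    return ad.AnnData(X=x, obs=obs, var=pd.DataFrame(index=gene_ids))


def simulate_correlated_expression(
    n_genes: int,
    design: pd.DataFrame,
    rho: float,
    seed: int = 0,
    total_sd: float = 1.0,
    condition_effects: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Gaussian log-expression with a planted intra-donor correlation.

    Shared-donor samples get a common donor effect of variance
    ``rho * total_sd**2`` plus independent noise of variance
    ``(1 - rho) * total_sd**2``, so the within-donor correlation is exactly
    ``rho``. Used to validate the consensus-correlation estimator.
    """
    if not -0.99 < rho < 0.99:
        raise ValueError("rho must lie in (-0.99, 0.99)")
    rng = np.random.default_rng(seed)
    donors = list(dict.fromkeys(design["donor_id"]))
    donor_eff = rng.normal(0.0, np.sqrt(max(rho, 0.0)) * total_sd, (n_genes, len(donors)))
    dcol = {d: k for k, d in enumerate(donors)}
    y = np.empty((n_genes, len(design)))
    for j, row in enumerate(design.itertuples(index=False)):
        eps = rng.normal(0.0, np.sqrt(1 - max(rho, 0.0)) * total_sd, n_genes)
        y[:, j] = donor_eff[:, dcol[row.donor_id]] + eps
        if condition_effects and row.condition in condition_effects:
            y[:, j] += condition_effects[row.condition]
    return pd.DataFrame(
        y,
        index=[f"G{i:05d}" for i in range(n_genes)],
        columns=design["sample_id"].to_numpy(),
    )
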