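"""Comparative-Ct (ΔΔCt) quantification and RNA-seq agreement.

Technical duplicates are averaged on the Ct scale, target Ct is normalized
to a reference gene (ΔCt), expressed relative to a baseline condition
(ΔΔCt, baseline = TNF alone in the study), and converted to relative
expression 2^(−ΔΔCt). Genes with Ct ≥ 30 under the TNF-stimulated gate
condition are excluded as unreliable.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

CT_GATE = 30.0

_REQUIRED = {"sample_id", "condition", "target", "replicate", "ct"}


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = _REQUIRED - set(records.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    bad = records["ct"].dropna() <= 0
    if bad.any():
        raise ValueError("Ct values must be positive (or missing)")
    return records


def _mean_ct(records: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic-mean Ct per sample x target over usable replicates."""
    usable = records.dropna(subset=["ct"])
    dropped = set(map(tuple, records[["sample_id", "target"]].values)) - set(
        map(tuple, usable[["sample_id", "target"]].values)
    )
    if dropped:
        warnings.warn(f"records with no usable replicate excluded: {sorted(dropped)[:5]}")
    return (
        usable.groupby(["sample_id", "condition", "target"], as_index=False)["ct"].mean()
    )


def ddct(
    records: pd.DataFrame,
    reference_gene: str,
    baseline_condition: str = "TNF",
) -> pd.DataFrame:
    """ΔΔCt relative quantification per gene x condition.

    ΔCt = mean Ct(target) − mean Ct(reference) per sample, averaged within
    condition; ΔΔCt = ΔCt(condition) − ΔCt(baseline); relative expression =
    2^(−ΔΔCt) and log2FC = −ΔΔCt. The baseline condition's relative
    expression is exactly 1.
    """
    mean_ct = _mean_ct(_check_records(records))
    ref = mean_ct[mean_ct["target"] == reference_gene].set_index("sample_id")["ct"]
    if ref.empty:
        raise ValueError(f"reference gene {reference_gene!r} absent from the Ct table")
    targets = mean_ct[mean_ct["target"] != reference_gene].copy()
    have_ref = targets["sample_id"].isin(ref.index)
    if (~have_ref).any():
        warnings.warn(
            "samples without reference Ct excluded: "
            f"{sorted(set(targets.loc[~have_ref, 'sample_id']))}"
        )
        targets = targets[have_ref]
    targets["dct"] = targets["ct"] - ref.reindex(targets["sample_id"]).to_numpy()
    per_cond = (
        targets.groupby(["target", "condition"], as_index=False)["dct"].mean()
    )
    base = per_cond[per_cond["condition"] == baseline_condition].set_index("target")["dct"]
    missing = set(per_cond["target"]) - set(base.index)
    if missing:
        raise ValueError(
            f"baseline condition {baseline_condition!r} missing for gene(s): {sorted(missing)}"
        )
    per_cond["ddct"] = per_cond["dct"] - base.reindex(per_cond["target"]).to_numpy()
    per_cond["log2fc"] = -per_cond["ddct"]
    per_cond["relative_expression"] = 2.0 ** per_cond["log2fc"]
    return per_cond[["target", "condition", "ddct", "log2fc", "relative_expression"]]


def ct_exclusion(
    records: pd.DataFrame,
    threshold: float = CT_GATE,
    gate_conditions: tuple[str, ...] = ("TNF",),
    per_donor: bool = False,
    design: pd.DataFrame | None = None,
) -> list[str]:
    """Genes retained by the Ct reliability gate (Ct ≥ threshold excluded).

    Default gates on the mean Ct across gate-condition samples; with
    ``per_donor`` (requires a design for the donor join) a gene is excluded
    if any donor's mean Ct in the gate condition reaches the threshold.
    """
    mean_ct = _mean_ct(_check_records(records))
    gate = mean_ct[mean_ct["condition"].isin(gate_conditions)]
    if gate.empty:
        raise ValueError(f"gate condition(s) {gate_conditions} absent from the Ct table")
    if per_donor:
        if design is None:
            raise ValueError("per_donor gating requires a design table")
        donor = design.set_index("sample_id")["donor_id"]
        gate = gate.assign(donor_id=donor.reindex(gate["sample_id"]).to_numpy())
        worst = gate.groupby(["target", "donor_id"])["ct"].mean().groupby("target").max()
    else:
        worst = gate.groupby("target")["ct"].mean()
    return [g for g in dict.fromkeys(mean_ct["target"]) if worst.get(g, np.inf) < threshold]


def crossplatform_agreement(
    qpcr_log2fc: pd.Series | np.ndarray, rnaseq_log2fc: pd.Series | np.ndarray
) -> dict:
    """Spearman agreement of qPCR and RNA-seq log2FCs over shared pairs."""
    a = np.asarray(qpcr_log2fc, dtype=float)
    b = np.asarray(rnaseq_log2fc, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired vectors must have equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 paired values")
    res = stats.spearmanr(a, b)
    return {"rho": float(res.statistic), "p": float(res.pvalue), "n": int(len(a))}
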