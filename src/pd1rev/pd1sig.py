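"""PD1-signalling statistics: dampening, responsive-gene calls, z-summaries.

Δlog2FC quantifies how sPD1 modifies the TNF response: the (TNF+sPD1 vs
control) log2FC minus the (TNF vs control) log2FC, with genes at Δ ≤ −0.5
called dampened. The compound responsive-gene filter requires a ≥50% change
under sPD1 on the TNF background (|log2FC| ≥ 0.585, unadjusted p ≤ 0.05)
that disappears when PD-L1 and/or PD-L2 is knocked out (|log2FC| < 0.585,
p ≥ 0.5 in the knockout contrast), and attributes the response to the
ligand(s) whose knockout abolishes it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

FC_THRESHOLD = 0.585  # |log2FC| for a 50% change: |log2(1.5)| rounds to 0.585
P1_DEFAULT = 0.05
P2_DEFAULT = 0.5
DELTA_THRESHOLD = -0.5


@dataclass
class DampeningSummary:
    """Distribution of per-gene Δlog2FC within one disease group."""

    group: str
    delta_log2fc: pd.Series
    threshold: float = DELTA_THRESHOLD

    @property
    def dampened_fraction(self) -> float:
        return float((self.delta_log2fc <= self.threshold).mean())

    @property
    def amplified_fraction(self) -> float:
        return float((self.delta_log2fc >= -self.threshold).mean())

    @property
    def mean_delta(self) -> float:
        return float(self.delta_log2fc.mean())

    @property
    def median_delta(self) -> float:
        return float(self.delta_log2fc.median())

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "threshold": self.threshold,
            "dampened_fraction": self.dampened_fraction,
            "amplified_fraction": self.amplified_fraction,
            "mean_delta": self.mean_delta,
            "median_delta": self.median_delta,
            "n_genes": int(len(self.delta_log2fc)),
        }


def delta_log2fc(
    table_spd1_vs_ctrl: pd.DataFrame,
    table_tnf_vs_ctrl: pd.DataFrame,
    threshold: float = DELTA_THRESHOLD,
    group: str = "",
) -> DampeningSummary:
    """Δ_g = log2FC(TNF+sPD1 vs control) − log2FC(TNF vs control).

    The dampened fraction counts genes with Δ at or below the threshold
    (boundary included); the amplified fraction mirrors it at −threshold.
    """
    a, b = table_spd1_vs_ctrl, table_tnf_vs_ctrl
    if set(a.index) != set(b.index):
        n = len(set(a.index) ^ set(b.index))
        raise ValueError(f"gene sets differ between tables ({n} genes in symmetric difference)")
    delta = a["log2fc"] - b["log2fc"].reindex(a.index)
    delta.name = "delta_log2fc"
    return DampeningSummary(group=group, delta_log2fc=delta, threshold=threshold)


def call_responsive(
    table_spd1_vs_tnf: pd.DataFrame,
    table_ko_l1_vs_tnf: pd.DataFrame,
    table_ko_l2_vs_tnf: pd.DataFrame,
    fc_threshold: float = FC_THRESHOLD,
    p1: float = P1_DEFAULT,
    p2: float = P2_DEFAULT,
    require_both: bool = False,
) -> pd.DataFrame:
    """Two-criterion sPD1-responsive gene caller with ligand attribution.

    Criterion 1: |log2FC| ≥ fc_threshold and raw p ≤ p1 in the sPD1-vs-TNF
    contrast. Criterion 2 (per ligand knockout): |log2FC| < fc_threshold and
    raw p ≥ p2 in that knockout-vs-TNF contrast. A gene is responsive if
    criterion 1 holds and criterion 2 holds for at least one ligand (both,
    if ``require_both``); attribution is "both" iff both knockouts qualify.
    Direction follows the sign of the criterion-1 log2FC.
    """
    if fc_threshold <= 0:
        raise ValueError("fc_threshold must be positive")
    if not (0 < p1 <= 1 and 0 <= p2 <= 1):
        raise ValueError("p-value thresholds out of range")
    tabs = {"sPD1": table_spd1_vs_tnf, "koL1": table_ko_l1_vs_tnf, "koL2": table_ko_l2_vs_tnf}
    genes = tabs["sPD1"].index
    for name, t in tabs.items():
        if set(t.index) != set(genes):
            raise ValueError(f"gene set of {name} table differs from sPD1 table")
    s = tabs["sPD1"]
    k1 = tabs["koL1"].reindex(genes)
    k2 = tabs["koL2"].reindex(genes)
    crit1 = (s["log2fc"].abs() >= fc_threshold) & (s["p"] <= p1)
    c2_l1 = (k1["log2fc"].abs() < fc_threshold) & (k1["p"] >= p2)
    c2_l2 = (k2["log2fc"].abs() < fc_threshold) & (k2["p"] >= p2)
    combined = (c2_l1 & c2_l2) if require_both else (c2_l1 | c2_l2)
    responsive = crit1 & combined
    attribution = np.select(
        [responsive & c2_l1 & c2_l2, responsive & c2_l1, responsive & c2_l2],
        ["both", "PD-L1", "PD-L2"],
        default="none",
    )
    return pd.DataFrame(
        {
            "passes_criterion1": crit1,
            "criterion2_pdl1": c2_l1,
            "criterion2_pdl2": c2_l2,
            "responsive": responsive,
            "attribution": attribution,
            "direction": np.where(s["log2fc"] >= 0, "up", "down"),
            "log2fc_spd1_vs_tnf": s["log2fc"],
        },
        index=genes,
    )


def zscore_summary(
    y: pd.DataFrame, design: pd.DataFrame, genes: list[str]
) -> pd.DataFrame:
    """Per-gene z-scores across samples, averaged within each condition.

    z uses the sample standard deviation (n−1); zero-variance genes are
    dropped with a warning. Row means over all samples are 0 by construction.
    """
    missing = [g for g in genes if g not in y.index]
    if missing:
        raise ValueError(f"genes not in the normalized matrix: {missing[:5]}")
    sub = y.loc[genes]
    sd = sub.std(axis=1, ddof=1)
    flat = sd[sd == 0]
    if len(flat):
        warnings.warn(f"dropping zero-variance gene(s): {list(flat.index)}")
        sub = sub.drop(index=flat.index)
        sd = sd.drop(index=flat.index)
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    cond = design.set_index("sample_id")["condition"].reindex(z.columns)
    return z.T.groupby(cond.to_numpy()).mean().T


def recover_truth(calls: pd.DataFrame, truth, group: str) -> dict:
    """Sensitivity, precision and attribution accuracy against planted truth.

    Planted responders are genes with a ligand dependency and a nonzero sPD1
    effect in the group. Precision is reported as None when nothing was
    called; attribution accuracy is computed over correctly called genes.
    """
    called = set(calls.index[calls["responsive"]])
    if not set(calls.index) & set(truth.gene_ids):
        raise ValueError("calls and truth share no gene identifiers")
    planted = set(truth.planted_responsive(group))
    hit = called & planted
    sensitivity = len(hit) / len(planted) if planted else None
    precision = len(hit) / len(called) if called else None
    dep = dict(zip(truth.gene_ids, truth.ligand_dependency))
    correct_attr = sum(1 for g in hit if calls.loc[g, "attribution"] == dep[g])
    attribution_accuracy = correct_attr / len(hit) if hit else None
    return {
        "n_planted": len(planted),
        "n_called": len(called),
        "n_correct": len(hit),
        "sensitivity": sensitivity,
        "precision": precision,
        "attribution_accuracy": attribution_accuracy,
    }
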