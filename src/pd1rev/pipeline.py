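"""End-to-end orchestration: simulate → normalize → model → diagnose → call → validate.

A RunConfig gathers every threshold of the analysis in one declarative
object (the responsive-gene cutoffs, the dampening threshold, the DEG FDR,
the qPCR Ct gate, the single-cell QC rules, bootstrap settings and all
simulation parameters). ``run_pipeline`` executes the per-group chain for NI
and RA, writes every intermediate table, and records a manifest of seeds,
input digests and stage timings; the run is a pure function of its config.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dex, diagnostics, io, pd1sig, qpcrval, simdata


@dataclass
class RunConfig:
    """All knobs of one pipeline run. Defaults are the study's thresholds."""

    out_dir: str = "pd1rev_run"
    counts_path: str | None = None  # TSV; simulated when absent
    design_path: str | None = None
    # analysis thresholds
    fc_threshold: float = pd1sig.FC_THRESHOLD
    p1: float = pd1sig.P1_DEFAULT
    p2: float = pd1sig.P2_DEFAULT
    delta_threshold: float = pd1sig.DELTA_THRESHOLD
    deg_fdr: float = 0.05
    ct_gate: float = qpcrval.CT_GATE
    qc_min_genes: int = 1000
    qc_max_mito: float = 0.25
    min_count: int = 10
    min_samples: int = 3
    # bootstrap
    bootstrap_replicates: int = 0  # 0 disables the (slow) stage
    bootstrap_contrast: str = "TNFsPD1_vs_TNF"
    # simulation
    seed: int = 0
    n_genes: int = 2000
    n_donors_per_group: int = 3
    n_responsive: int = 200
    spd1_lfc: float = 1.5
    frac_tnf_de: float = 0.15
    tnf_lfc_scale: float = 1.5
    mean_library_size: float = 1e6
    sigma_donor: float = 0.3
    qpcr_noise_sd: float = 0.2
    qpcr_n_targets: int = 6
    groups: tuple[str, ...] = ("NI", "RA")

    def validate(self) -> list[str]:
        problems = []
        if self.fc_threshold <= 0:
            problems.append("fc_threshold must be positive")
        for name in ("p1", "p2", "deg_fdr", "qc_max_mito"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                problems.append(f"{name} must lie in [0, 1]")
        if self.delta_threshold >= 0:
            problems.append("delta_threshold must be negative (dampening cut)")
        if self.ct_gate <= 0:
            problems.append("ct_gate must be positive")
        if self.qc_min_genes < 1 or self.min_count < 1 or self.min_samples < 1:
            problems.append("count thresholds must be >= 1")
        if self.bootstrap_replicates and self.bootstrap_replicates < 50:
            problems.append("bootstrap_replicates must be 0 or >= 50")
        return problems


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def validate_inputs(counts_path, design_path) -> list[str]:
    """Check CountMatrix / SampleDesign invariants without mutating inputs."""
    counts = io.read_counts_tsv(counts_path)
    design = io.read_design(design_path)
    problems = simdata.validate_design(design)
    if counts.index.duplicated().any():
        problems.append("duplicate gene identifiers in counts")
    if counts.columns.duplicated().any():
        problems.append("duplicate sample identifiers in counts")
    vals = counts.to_numpy()
    if not np.issubdtype(vals.dtype, np.number) or np.any(vals != np.round(vals)):
        problems.append("counts must be integers")
    neg = np.argwhere(vals < 0)
    for i, j in neg[:10]:
        problems.append(
            f"negative count at gene {counts.index[i]}, sample {counts.columns[j]}"
        )
    missing = set(design["sample_id"]) - set(counts.columns)
    if missing:
        problems.append(f"design samples absent from counts: {sorted(missing)[:5]}")
    return problems


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full chain per disease group; returns the manifest."""
    problems = config.validate()
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": [], "outputs": {}}
    t0 = time.time()

    def stage(name):
        manifest["stages"].append({"name": name, "t": round(time.time() - t0, 3)})

    # --- inputs ---------------------------------------------------------
    truth = None
    if config.counts_path:
        counts = io.read_counts_tsv(config.counts_path)
        design = io.read_design(config.design_path)
        bad = validate_inputs(config.counts_path, config.design_path)
        if bad:
            raise ValueError("input validation failed: " + "; ".join(bad))
        manifest["inputs"] = {
            "counts": _digest(Path(config.counts_path)),
            "design": _digest(Path(config.design_path)),
        }
    else:
        design = simdata.make_design(config.n_donors_per_group, groups=config.groups)
        truth = simdata.make_truth(
            design,
            n_genes=config.n_genes,
            seed=config.seed,
            n_responsive=config.n_responsive,
            spd1_lfc=config.spd1_lfc,
            frac_tnf_de=config.frac_tnf_de,
            tnf_lfc_scale=config.tnf_lfc_scale,
            mean_library_size=config.mean_library_size,
            sigma_donor=config.sigma_donor,
        )
        counts = simdata.simulate_bulk_counts(truth, design)
        io.write_counts_tsv(counts, out / "counts.tsv")
        io.write_design(design, out / "design.tsv")
        io.write_truth_json(truth, out / "truth.json")
        manifest["outputs"]["counts"] = "counts.tsv"
    stage("inputs")

    # --- per-group analysis --------------------------------------------
    summary: dict = {"groups": {}}
    for group in config.groups:
        res = dex.run_group_analysis(
            counts, design, group=group,
            min_count=config.min_count, min_samples=config.min_samples,
        )
        gdir = out / group
        gdir.mkdir(exist_ok=True)
        gsum: dict = {
            "n_kept_genes": len(res.normalized.kept_genes),
            "consensus_rho": res.ebayes.consensus_rho,
            "deg_counts": {},
        }
        for name, table in res.tables.items():
            io.write_contrast_table(table, gdir / f"contrast_{name}.tsv")
            gsum["deg_counts"][name] = int((table["p_adj"] <= config.deg_fdr).sum())
        stage(f"dex_{group}")

        rp = diagnostics.residual_pca(res.normalized.log2_cpm, res.design)
        rp.scores.iloc[:, :2].to_csv(gdir / "residual_pca_scores.tsv", sep="\t")
        gsum["residual_pc1_var"] = float(rp.variance_explained[0])
        stage(f"diagnostics_{group}")

        damp = pd1sig.delta_log2fc(
            res.tables["TNFsPD1_vs_control"], res.tables["TNF_vs_control"],
            threshold=config.delta_threshold, group=group,
        )
        damp.delta_log2fc.to_csv(gdir / "delta_log2fc.tsv", sep="\t")
        io.write_json(damp.to_dict(), gdir / "dampening.json")
        gsum["dampening"] = damp.to_dict()

        calls = pd1sig.call_responsive(
            res.tables["TNFsPD1_vs_TNF"],
            res.tables["KO_PDL1_vs_TNF"],
            res.tables["KO_PDL2_vs_TNF"],
            fc_threshold=config.fc_threshold, p1=config.p1, p2=config.p2,
        )
        calls.to_csv(gdir / "responsive_calls.tsv", sep="\t")
        gsum["n_responsive"] = int(calls["responsive"].sum())
        responsive_genes = list(calls.index[calls["responsive"]])
        if responsive_genes:
            zs = pd1sig.zscore_summary(
                res.normalized.log2_cpm, res.design, responsive_genes
            )
            zs.to_csv(gdir / "zscore_summary.tsv", sep="\t")
        if truth is not None:
            gsum["recovery"] = pd1sig.recover_truth(calls, truth, group)
        stage(f"pd1sig_{group}")

        if config.bootstrap_replicates:
            bs = diagnostics.bootstrap_stability(
                counts, design, config.bootstrap_contrast,
                n_replicates=config.bootstrap_replicates,
                seed=config.seed + 7, group=group,
                min_count=config.min_count, min_samples=config.min_samples,
            )
            pd.DataFrame({"replicate": range(len(bs.rhos)), "rho": bs.rhos}).to_csv(
                gdir / "bootstrap_rhos.tsv", sep="\t", index=False
            )
            io.write_json(
                {
                    "contrast": bs.contrast_name,
                    "median_rho": bs.median_rho,
                    "category": bs.category,
                    "n_replicates": bs.n_replicates,
                    "n_redrawn": bs.n_redrawn,
                    "seed": bs.seed,
                },
                gdir / "bootstrap_summary.json",
            )
            gsum["bootstrap"] = {"median_rho": bs.median_rho, "category": bs.category}
            stage(f"bootstrap_{group}")
        summary["groups"][group] = gsum

    # --- qPCR validation (simulated studies only) ------------------------
    if truth is not None:
        rng = np.random.default_rng(config.seed + 13)
        null_genes = [
            g for g, d, t, s in zip(
                truth.gene_ids, truth.ligand_dependency,
                np.abs(truth.tnf_log2fc.to_numpy()).sum(axis=1),
                np.abs(truth.spd1_log2fc.to_numpy()).sum(axis=1),
            )
            if d == "none" and t == 0 and s == 0
        ]
        reference = null_genes[0]
        candidates = truth.planted_responsive(config.groups[0]) or truth.gene_ids[:10]
        targets = list(rng.choice(candidates, size=min(config.qpcr_n_targets, len(candidates)), replace=False))
        ct = simdata.simulate_qpcr(
            truth, design, targets, reference,
            noise_sd=config.qpcr_noise_sd, seed=config.seed + 17,
        )
        io.write_ct_table(ct, out / "qpcr_ct.csv")
        retained = qpcrval.ct_exclusion(ct, threshold=config.ct_gate)
        rel = qpcrval.ddct(ct, reference_gene=reference, baseline_condition="TNF")
        rel = rel[rel["target"].isin(retained)]
        rel.to_csv(out / "qpcr_relative_expression.tsv", sep="\t", index=False)
        qp = rel[rel["condition"] == "TNF_sPD1"].set_index("target")["log2fc"]
        seq_tab = None
        g0 = config.groups[0]
        # compare against the RNA-seq sPD1-vs-TNF log2FCs of the first group
        seq = None
        seq_path = out / g0 / "contrast_TNFsPD1_vs_TNF.tsv"
        if seq_path.exists():
            seq_tab = io.read_contrast_table(seq_path)
            shared = [g for g in qp.index if g in seq_tab.index]
            if len(shared) >= 3:
                seq = qpcrval.crossplatform_agreement(
                    qp.loc[shared], seq_tab.loc[shared, "log2fc"]
                )
        summary["qpcr"] = {
            "reference_gene": reference,
            "targets": targets,
            "n_retained_after_ct_gate": len(retained),
            "crossplatform": seq,
        }
        stage("qpcr")

    manifest["summary"] = summary
    io.write_json(manifest, out / "manifest.json")
    return manifest
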