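"""Dampening, responsive-gene calling, z-summaries, truth recovery."""

import numpy as np
import pandas as pd
import pytest

from pd1rev import dex, pd1sig, simdata


def _table(genes, log2fc, p):
    return pd.DataFrame(
        {"log2fc": log2fc, "p": p, "p_adj": p, "t": 0.0, "avg_expr": 5.0},
        index=genes,
    )


class TestDeltaLog2fc:
    def test_identical_tables_give_zero_delta(self):
        genes = list("abcde")
        t = _table(genes, [1, -1, 0.2, 2, 0], [0.5] * 5)
        summ = pd1sig.delta_log2fc(t, t)
        assert (summ.delta_log2fc == 0).all()
        assert summ.dampened_fraction == 0.0

    def test_boundary_counts_as_dampened(self):
        genes = list("abcde")
        a = _table(genes, [-0.6, -0.4, 0.2, -0.5, 0.1], [0.5] * 5)
        b = _table(genes, [0.0] * 5, [0.5] * 5)
        summ = pd1sig.delta_log2fc(a, b, threshold=-0.5)
        assert summ.dampened_fraction == pytest.approx(0.4)  # -0.6 and -0.5

    def test_gene_set_mismatch_rejected(self):
        a = _table(list("abc"), [0, 0, 0], [1, 1, 1])
        b = _table(list("abd"), [0, 0, 0], [1, 1, 1])
        with pytest.raises(ValueError, match="symmetric difference"):
            pd1sig.delta_log2fc(a, b)

    def test_planted_ni_only_suppression_creates_asymmetry(self, design_two_groups):
        """sPD1 dampening planted in NI only -> NI fraction > RA fraction."""
        wins = 0
        n_sims = 25
        for run in range(n_sims):
            truth = simdata.make_truth(
                design_two_groups, n_genes=600, seed=1200 + run, frac_tnf_de=0.25,
                tnf_lfc_scale=1.5, n_responsive=0, dampen_group="NI",
                dampen_frac=0.4, dampen_delta=-1.0, mean_library_size=5e5,
            )
            counts = simdata.simulate_bulk_counts(truth, design_two_groups)
            fracs = {}
            for g in ("NI", "RA"):
                res = dex.run_group_analysis(
                    counts, design_two_groups, group=g,
                    contrasts=("TNF_vs_control", "TNFsPD1_vs_control"),
                )
                fracs[g] = pd1sig.delta_log2fc(
                    res.tables["TNFsPD1_vs_control"], res.tables["TNF_vs_control"],
                    group=g,
                ).dampened_fraction
            if fracs["NI"] > fracs["RA"]:
                wins += 1
        assert wins >= int(0.95 * n_sims)

    def test_delta_equals_direct_spd1_vs_tnf_contrast(self, design_one_group):
        """Contrast algebra: (sPD1 vs ctl) − (TNF vs ctl) = sPD1 vs TNF."""
        truth = simdata.make_truth(
            design_one_group, n_genes=300, seed=55, mean_library_size=5e5,
            n_responsive=30,
        )
        counts = simdata.simulate_bulk_counts(truth, design_one_group)
        res = dex.run_group_analysis(counts, design_one_group, group="NI")
        delta = pd1sig.delta_log2fc(
            res.tables["TNFsPD1_vs_control"], res.tables["TNF_vs_control"]
        ).delta_log2fc
        direct = res.tables["TNFsPD1_vs_TNF"]["log2fc"]
        assert np.allclose(delta, direct.reindex(delta.index), atol=1e-8)


class TestCallResponsive:
    def test_single_ligand_attribution(self):
        genes = ["g"]
        calls = pd1sig.call_responsive(
            _table(genes, [0.8], [0.01]),
            _table(genes, [0.1], [0.8]),
            _table(genes, [0.7], [0.01]),
        )
        row = calls.loc["g"]
        assert row["responsive"] and row["attribution"] == "PD-L1"
        assert row["direction"] == "up"

    def test_criterion1_fold_change_floor(self):
        genes = ["g"]
        calls = pd1sig.call_responsive(
            _table(genes, [0.3], [0.001]),
            _table(genes, [0.0], [0.9]),
            _table(genes, [0.0], [0.9]),
        )
        assert not calls.loc["g", "responsive"]  # 0.3 < 0.585

    def test_both_attribution_and_down_direction(self):
        genes = ["g"]
        calls = pd1sig.call_responsive(
            _table(genes, [-0.9], [0.02]),
            _table(genes, [0.0], [0.9]),
            _table(genes, [0.0], [0.9]),
        )
        row = calls.loc["g"]
        assert row["responsive"] and row["attribution"] == "both"
        assert row["direction"] == "down"

    def test_boundaries_exactly_as_printed(self):
        genes = ["g"]
        # |log2FC| = 0.585 passes criterion 1; 0.585 fails criterion 2 (<)
        calls = pd1sig.call_responsive(
            _table(genes, [0.585], [0.05]),
            _table(genes, [0.585], [0.9]),
            _table(genes, [0.0], [0.5]),
        )
        row = calls.loc["g"]
        assert row["passes_criterion1"]
        assert not row["criterion2_pdl1"]
        assert row["criterion2_pdl2"]  # p = 0.5 boundary passes (>=)

    def test_monotone_in_p_thresholds(self):
        """Raising p1 or lowering p2 can only add responsive calls; the
        fold-change threshold is genuinely non-monotone (it loosens
        criterion 1 while tightening criterion 2)."""
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(300)]
        t1 = _table(genes, rng.normal(0, 1, 300), rng.uniform(size=300))
        t2 = _table(genes, rng.normal(0, 0.4, 300), rng.uniform(size=300))
        t3 = _table(genes, rng.normal(0, 0.4, 300), rng.uniform(size=300))
        base = pd1sig.call_responsive(t1, t2, t3)
        called = set(base.index[base["responsive"]])
        higher_p1 = pd1sig.call_responsive(t1, t2, t3, p1=0.2)
        lower_p2 = pd1sig.call_responsive(t1, t2, t3, p2=0.3)
        assert called <= set(higher_p1.index[higher_p1["responsive"]])
        assert called <= set(lower_p2.index[lower_p2["responsive"]])
        # criterion-2 tightening under a lower fc threshold can remove calls
        looser_fc = pd1sig.call_responsive(t1, t2, t3, fc_threshold=0.3)
        gained_c1 = looser_fc["passes_criterion1"].sum() >= base["passes_criterion1"].sum()
        lost_c2 = (
            looser_fc["criterion2_pdl1"].sum() <= base["criterion2_pdl1"].sum()
        )
        assert gained_c1 and lost_c2

    def test_require_both_flag(self):
        genes = ["g"]
        tabs = (
            _table(genes, [1.0], [0.01]),
            _table(genes, [0.0], [0.9]),
            _table(genes, [1.0], [0.01]),
        )
        assert pd1sig.call_responsive(*tabs).loc["g", "responsive"]
        assert not pd1sig.call_responsive(*tabs, require_both=True).loc["g", "responsive"]

    def test_invalid_thresholds_rejected(self):
        t = _table(["g"], [1.0], [0.5])
        with pytest.raises(ValueError):
            pd1sig.call_responsive(t, t, t, fc_threshold=-1)


class TestSymmetricNull:
    def test_dampened_and_amplified_fractions_agree(self, design_one_group):
        diffs = []
        for run in range(20):
            truth = simdata.make_truth(
                design_one_group, n_genes=800, seed=1500 + run, frac_tnf_de=0.2,
                n_responsive=0, mean_library_size=5e5,
            )
            counts = simdata.simulate_bulk_counts(truth, design_one_group)
            res = dex.run_group_analysis(
                counts, design_one_group, group="NI",
                contrasts=("TNF_vs_control", "TNFsPD1_vs_control"),
            )
            s = pd1sig.delta_log2fc(
                res.tables["TNFsPD1_vs_control"], res.tables["TNF_vs_control"]
            )
            diffs.append(s.dampened_fraction - s.amplified_fraction)
            assert s.dampened_fraction + s.amplified_fraction <= 1.0
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 3 * max(se, 1e-6)


class TestZscoreSummary:
    def test_standardization_identity(self, design_one_group):
        rng = np.random.default_rng(6)
        y = pd.DataFrame(
            rng.normal(size=(10, 15)), columns=design_one_group["sample_id"],
            index=[f"g{i}" for i in range(10)],
        )
        sub = y.sub(y.mean(axis=1), axis=0).div(y.std(axis=1, ddof=1), axis=0)
        assert np.allclose(sub.mean(axis=1), 0, atol=1e-8)
        assert np.allclose(sub.std(axis=1, ddof=1), 1, atol=1e-8)
        zs = pd1sig.zscore_summary(y, design_one_group, list(y.index))
        assert zs.shape == (10, 5)

    def test_hand_standardization_two_conditions(self):
        design = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(6)],
                "donor_id": [f"d{i % 3}" for i in range(6)],
                "disease_group": "NI",
                "condition": ["control"] * 3 + ["TNF"] * 3,
            }
        )
        y = pd.DataFrame([[1, 1, 1, 3, 3, 3]], index=["g"], columns=design["sample_id"])
        zs = pd1sig.zscore_summary(y, design, ["g"])
        sd = np.std([1, 1, 1, 3, 3, 3], ddof=1)
        assert zs.loc["g", "control"] == pytest.approx(-1 / sd)
        assert zs.loc["g", "TNF"] == pytest.approx(1 / sd)

    def test_zero_variance_gene_dropped_with_warning(self, design_one_group):
        y = pd.DataFrame(
            np.vstack([np.ones(15), np.arange(15.0)]),
            index=["flat", "ok"], columns=design_one_group["sample_id"],
        )
        with pytest.warns(UserWarning, match="flat"):
            zs = pd1sig.zscore_summary(y, design_one_group, ["flat", "ok"])
        assert list(zs.index) == ["ok"]


class TestRecoverTruth:
    def test_perfect_calls(self, signal_truth):
        planted = signal_truth.planted_responsive("NI")
        calls = pd.DataFrame(
            {
                "responsive": [g in planted for g in signal_truth.gene_ids],
                "attribution": [
                    d if d != "none" else "none"
                    for d in signal_truth.ligand_dependency
                ],
            },
            index=signal_truth.gene_ids,
        )
        rec = pd1sig.recover_truth(calls, signal_truth, "NI")
        assert rec["sensitivity"] == 1.0
        assert rec["precision"] == 1.0
        assert rec["attribution_accuracy"] == 1.0

    def test_empty_call_set(self, signal_truth):
        calls = pd.DataFrame(
            {"responsive": False, "attribution": "none"}, index=signal_truth.gene_ids
        )
        rec = pd1sig.recover_truth(calls, signal_truth, "NI")
        assert rec["sensitivity"] == 0.0
        assert rec["precision"] is None

    def test_disjoint_gene_sets_rejected(self, signal_truth):
        calls = pd.DataFrame({"responsive": [True], "attribution": ["both"]}, index=["zz"])
        with pytest.raises(ValueError, match="share no gene"):
            pd1sig.recover_truth(calls, signal_truth, "NI")
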