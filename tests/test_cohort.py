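import numpy as np
import pandas as pd
import pytest
from scipy import stats

import smad4sig as s
from smad4sig.synth import CohortTable


def _cohort_from_calls(alterations: dict[str, list[str]], expression=None):
    """CohortTable from {sample: [altered genes]}."""
    samples = pd.Index(sorted(alterations), name="sample_id")
    genes = sorted({g for v in alterations.values() for g in v} | {"SMAD4"})
    calls = pd.DataFrame(False, index=samples, columns=genes)
    for smp, gl in alterations.items():
        for g in gl:
            calls.loc[smp, g] = True
    if expression is None:
        expression = pd.DataFrame(1.0, index=samples, columns=["X"])
    surv = pd.DataFrame({"time": 1.0, "event": 1}, index=samples)
    return CohortTable(expression, calls, surv)


class TestPathwayStatus:
    def test_apc_only_sets_wnt_alone(self):
        ct = _cohort_from_calls({"s1": ["APC"]})
        flags = s.assign_pathway_status(ct)
        assert bool(flags.loc["s1", "WNT"])
        assert not flags.loc["s1", ["SMAD4", "TGFB_other", "BMP", "RTK_RAS", "TP53", "PI3K"]].any()

    def test_smad4_and_receptor_set_both_tgfb_flags(self):
        ct = _cohort_from_calls({"s1": ["SMAD4", "TGFBR2"]})
        flags = s.assign_pathway_status(ct)
        assert bool(flags.loc["s1", "SMAD4"]) and bool(flags.loc["s1", "TGFB_other"])

    def test_no_alterations_all_false(self):
        ct = _cohort_from_calls({"s1": []})
        assert not s.assign_pathway_status(ct).loc["s1"].any()

    def test_unknown_pathway_rejected(self):
        ct = _cohort_from_calls({"s1": ["APC"]})
        with pytest.raises(ValueError):
            s.assign_pathway_status(ct, {"NOTCH": ["NOTCH1"]})


class TestSelectCohort:
    def test_selection_rules(self):
        ct = _cohort_from_calls(
            {
                "mut": ["APC", "SMAD4"],
                "mut_excl": ["APC", "SMAD4", "SMAD2"],   # other TGF-beta variant
                "ctrl": ["APC"],
                "no_wnt": ["SMAD4"],                     # excluded entirely
            }
        )
        mutant, control = s.select_cohort(s.assign_pathway_status(ct))
        assert list(mutant) == ["mut"]
        assert list(control) == ["ctrl"]

    def test_empty_sets_rejected(self):
        ct = _cohort_from_calls({"s1": ["APC"]})
        with pytest.raises(ValueError):
            s.select_cohort(s.assign_pathway_status(ct))


class TestVolcano:
    def _table(self, mut_vals, ctrl_vals):
        samples = [f"m{i}" for i in range(len(mut_vals))] + [f"c{i}" for i in range(len(ctrl_vals))]
        idx = pd.Index(samples, name="sample_id")
        expr = pd.DataFrame({"X": list(mut_vals) + list(ctrl_vals)}, index=idx)
        calls = pd.DataFrame(False, index=idx, columns=["SMAD4"])
        surv = pd.DataFrame({"time": 1.0, "event": 1}, index=idx)
        ct = CohortTable(expr, calls, surv)
        mutant = idx[: len(mut_vals)]
        control = idx[len(mut_vals):]
        return ct, mutant, control

    def test_identical_groups_are_null(self):
        ct, m, c = self._table([1, 2, 3], [1, 2, 3])
        res = s.volcano_mut_vs_wt(ct, ["X"], m, c)
        assert res.loc[0, "pvalue"] == 1.0 and res.loc[0, "median_log2fc"] == 0.0

    def test_exact_small_sample_p(self):
        # complete separation of 3 vs 3: two-sided exact p = 2/20 = 0.1
        ct, m, c = self._table([1, 2, 3], [4, 5, 6])
        res = s.volcano_mut_vs_wt(ct, ["X"], m, c)
        assert res.loc[0, "pvalue"] == pytest.approx(0.1)

    def test_scaling_mutants_shifts_median_lfc(self):
        ct, m, c = self._table([4, 8, 12], [1, 2, 3])
        res = s.volcano_mut_vs_wt(ct, ["X"], m, c)
        assert res.loc[0, "median_log2fc"] == pytest.approx(2.0, abs=0.6)

    def test_absent_gene_skipped_with_warning(self):
        ct, m, c = self._table([1, 2, 3], [4, 5, 6])
        with pytest.warns(UserWarning):
            res = s.volcano_mut_vs_wt(ct, ["X", "missing"], m, c)
        assert list(res["gene"]) == ["X"]


class TestSubgroups:
    def _flags(self):
        idx = pd.Index([f"s{i}" for i in range(24)], name="sample_id")
        flags = pd.DataFrame(False, index=idx, columns=list(s.cohort.FLAG_COLUMNS))
        flags["WNT"] = True
        flags.iloc[12:, flags.columns.get_loc("SMAD4")] = True
        flags.iloc[list(range(6, 12)) + list(range(18, 24)),
                   flags.columns.get_loc("TP53")] = True
        return flags

    def test_group_conventions(self):
        flags = self._flags()
        mutant, control = s.select_cohort(flags)
        group = s.assemble_subgroups(flags, mutant, control, "TP53")
        assert group.loc["s0"] == "G1"    # WT, context absent
        assert group.loc["s6"] == "G2"    # WT, context present
        assert group.loc["s12"] == "G3"   # mutant, context absent
        assert group.loc["s18"] == "G4"   # mutant, context present

    def test_groups_partition_cohort(self):
        flags = self._flags()
        mutant, control = s.select_cohort(flags)
        group = s.assemble_subgroups(flags, mutant, control, "TP53")
        assert len(group) == len(mutant) + len(control)
        assert set(group.unique()) == {"G1", "G2", "G3", "G4"}

    def test_underfilled_group_rejected(self):
        flags = self._flags()
        flags.iloc[6:12, flags.columns.get_loc("TP53")] = False  # empty G2
        mutant, control = s.select_cohort(flags)
        with pytest.raises(ValueError, match="G2"):
            s.assemble_subgroups(flags, mutant, control, "TP53")


class TestKwDunn:
    def test_hand_example_matches_brute_force_rank_formula(self):
        groups = [np.array([1, 2, 3]), np.array([4, 5, 6]),
                  np.array([7, 8, 9]), np.array([10, 11, 12])]
        H, p, pairs = s.kw_dunn(groups)
        # independent oracle: H = 12/(N(N+1)) * sum(R_j^2/n_j) - 3(N+1)
        N = 12
        ranks = stats.rankdata(np.concatenate(groups))
        R = [ranks[:3].sum(), ranks[3:6].sum(), ranks[6:9].sum(), ranks[9:].sum()]
        H_brute = 12.0 / (N * (N + 1)) * sum(r**2 / 3 for r in R) - 3 * (N + 1)
        assert H == pytest.approx(H_brute)
        assert H == pytest.approx(10.385, abs=1e-3)
        assert p == pytest.approx(stats.chi2.sf(H_brute, 3))

    def test_identical_values_conventionally_null(self):
        H, p, pairs = s.kw_dunn([np.ones(4)] * 4)
        assert H == 0.0 and p == 1.0 and all(v == 1.0 for v in pairs.values())

    def test_holm_adjustment_hand_example(self):
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.04], method="holm")[1]
        assert np.allclose(adj, [0.02, 0.04])

    def test_null_calibration(self):
        rng = np.random.default_rng(0)
        pvals = [s.kw_dunn([rng.normal(size=8) for _ in range(4)])[1] for _ in range(400)]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            s.kw_dunn([np.ones(2), np.ones(4), np.ones(4), np.ones(4)])


class TestDependenceDecision:
    BASE = {
        "G1G3": 0.01, "G1G4": 0.02, "G2G3": 0.01, "G2G4": 0.03,
        "G1G2": 0.5, "G3G4": 0.6,
    }

    def _decide(self, pairs, human=1.0, mouse=1.0):
        return s.smad4_dependence_decision(
            {"RTK_RAS": pairs}, {"RTK_RAS": 0.001}, human, mouse
        )

    def test_all_criteria_met(self):
        dep, failed = self._decide(dict(self.BASE))
        assert dep and failed == "none"

    def test_within_status_difference_fails_criterion_2(self):
        dep, failed = self._decide(dict(self.BASE, G1G2=0.01))
        assert not dep and failed == "2"

    def test_direction_mismatch_fails_criterion_3(self):
        dep, failed = self._decide(dict(self.BASE), human=-1.0, mouse=1.0)
        assert not dep and failed == "3"

    def test_cross_pair_nonsignificance_fails_criterion_1(self):
        dep, failed = self._decide(dict(self.BASE, G1G3=0.2))
        assert not dep and failed == "1"

    def test_missing_pair_rejected(self):
        pairs = dict(self.BASE)
        del pairs["G2G4"]
        with pytest.raises(ValueError, match="G2G4"):
            self._decide(pairs)

    def test_all_mode_requires_every_context(self):
        good, bad = dict(self.BASE), dict(self.BASE, G1G3=0.9)
        dep_all, _ = s.smad4_dependence_decision(
            {"A": good, "B": bad}, {"A": 0.01, "B": 0.01}, 1.0, 1.0, mode="all")
        dep_any, _ = s.smad4_dependence_decision(
            {"A": good, "B": bad}, {"A": 0.01, "B": 0.01}, 1.0, 1.0, mode="any")
        assert not dep_all and dep_any


class TestScreenRecovery:
    def test_planted_dependence_recovered(self, cohort_sim):
        _, ct, truth = cohort_sim
        genes = truth.loc[truth["class"] != "survival_cutpoint", "entity"].tolist()
        dirs = dict(zip(truth["entity"],
                        np.where(truth["effect"] == 0, 1.0, np.sign(truth["effect"]))))
        screen = s.smad4_dependence_screen(ct, genes, dirs)
        m = screen.merge(truth, left_on="gene", right_on="entity")
        dep = m[m["class"] == "smad4_dependent"]
        conf = m[m["class"] == "context_confounded"]
        other = m[m["class"] != "smad4_dependent"]
        assert dep["smad4_dependent"].mean() >= 0.8
        assert 1.0 - other["smad4_dependent"].mean() >= 0.9
        assert conf["failed_criterion"].isin(["1", "2"]).all()

    def test_decision_invariant_to_sample_order(self, cohort_sim):
        _, ct, truth = cohort_sim
        genes = truth.loc[truth["class"] == "smad4_dependent", "entity"].tolist()[:3]
        dirs = {g: np.sign(truth.set_index("entity").loc[g, "effect"]) for g in genes}
        a = s.smad4_dependence_screen(ct, genes, dirs)
        perm = np.random.default_rng(1).permutation(len(ct.expression))
        ct2 = CohortTable(ct.expression.iloc[perm], ct.variants.iloc[perm],
                          ct.survival.iloc[perm])
        b = s.smad4_dependence_screen(ct2, genes, dirs)
        pd.testing.assert_frame_equal(a, b)
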