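"""Shift-ability screening: TAS filtering, the ES_S - ES_R statistic,
knockdown assessment and target concordance."""

import numpy as np
import pandas as pd
import pytest

from synergyshift import (
    GeneSet,
    PerturbationCompendium,
    RankedProfile,
    UnscorableSetError,
    aggregate_perturbagen,
    assess_knockdown,
    call_r_to_s,
    concordant_targets,
    filter_profiles,
    prioritize_targets,
    shift_ability,
    weighted_ks_es,
)
from synergyshift.screen import ShiftResult, TargetPriority

from oracles import brute_force_es, linear_interp_percentile


def _compendium(values, meta_rows):
    meta = pd.DataFrame(meta_rows).set_index("experiment_id")
    return PerturbationCompendium(values, meta)


def _meta(exp, pert="c1", ptype="compound", target=None, cell="A", tas=0.9):
    return {
        "experiment_id": exp,
        "perturbagen_id": pert,
        "type": ptype,
        "target": target,
        "cell_line": cell,
        "dose": 1.0,
        "time": "24h",
        "tas": tas,
    }


class TestFilterProfiles:
    def _ten(self, rng):
        genes = [f"g{i}" for i in range(5)]
        vals = pd.DataFrame(
            rng.normal(0, 1, (5, 10)), index=genes, columns=[f"e{i}" for i in range(10)]
        )
        tas = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0]
        meta = [_meta(f"e{i}", tas=t) for i, t in enumerate(tas)]
        return _compendium(vals, meta)

    def test_grid_of_tas_keeps_seven(self, rng):
        comp = self._ten(rng)
        kept = filter_profiles(comp, tas_min=0.4)
        assert kept.values.shape[1] == 7

    def test_boundary_is_inclusive(self, rng):
        comp = self._ten(rng)
        kept = filter_profiles(comp, tas_min=0.4)
        assert "e3" in kept.values.columns  # tas exactly 0.4

    def test_empty_result_is_warning_not_error(self, rng, caplog):
        import logging

        comp = self._ten(rng)
        with caplog.at_level(logging.WARNING, logger="synergyshift.screen"):
            empty = filter_profiles(comp, tas_min=1.0 + 1e-9)
        assert empty.values.shape[1] == 0
        assert any("removed every experiment" in r.message for r in caplog.records)

    def test_gene_universe_restriction(self, rng):
        comp = self._ten(rng)
        kept = filter_profiles(comp, tas_min=0.0, gene_universe=["g0", "g2"])
        assert kept.values.index.tolist() == ["g0", "g2"]
        with pytest.raises(ValueError, match="absent"):
            filter_profiles(comp, gene_universe=["g0", "zz"])


class TestShiftAbility:
    def test_identical_sets_give_zero(self, rng):
        profile = pd.Series(rng.normal(0, 1, 50), index=[f"g{i}" for i in range(50)])
        s = GeneSet("sig", [f"g{i}" for i in range(5, 15)])
        res = shift_ability(profile, s, s)
        assert res.shift_ability == 0.0

    def test_extreme_construction_reaches_two(self):
        genes = [f"g{i:03d}" for i in range(100)]
        profile = pd.Series(np.arange(100, 0, -1, dtype=float), index=genes)
        s_sig = GeneSet("S", genes[:5])
        r_sig = GeneSet("R", genes[95:])
        res = shift_ability(profile, r_sig, s_sig)
        assert res.es_s == pytest.approx(1.0)
        assert res.es_r == pytest.approx(-1.0)
        assert res.shift_ability == pytest.approx(2.0)
        assert res.r_suppressed and res.s_induced

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(77)
        genes = np.array([f"g{i:04d}" for i in range(1000)])
        vals = rng.normal(0, 1, 1000)
        profile = pd.Series(vals, index=genes)
        s_sig = GeneSet("S", rng.choice(genes, 20, replace=False).tolist())
        r_sig = GeneSet("R", rng.choice(genes, 20, replace=False).tolist())
        res = shift_ability(profile, r_sig, s_sig)
        order = np.lexsort((genes, -vals))
        ranked_scores = vals[order]
        es_s = brute_force_es(ranked_scores, np.isin(genes[order], np.array(s_sig.members)), 1.0)
        es_r = brute_force_es(ranked_scores, np.isin(genes[order], np.array(r_sig.members)), 1.0)
        assert res.shift_ability == pytest.approx(es_s - es_r, abs=1e-12)

    def test_unscorable_signature_is_named(self, rng):
        profile = pd.Series(rng.normal(0, 1, 10), index=[f"g{i}" for i in range(10)])
        with pytest.raises(UnscorableSetError, match="R signature"):
            shift_ability(profile, GeneSet("R", ["zz"]), GeneSet("S", ["g1"]))
        with pytest.raises(UnscorableSetError, match="S signature"):
            shift_ability(profile, GeneSet("R", ["g1"]), GeneSet("S", ["zz"]))

    def test_bounds_on_random_profiles(self, rng):
        genes = [f"g{i}" for i in range(60)]
        r_sig = GeneSet("R", genes[:6])
        s_sig = GeneSet("S", genes[6:12])
        for _ in range(200):
            profile = pd.Series(rng.normal(0, 1, 60), index=genes)
            res = shift_ability(profile, r_sig, s_sig)
            assert -2.0 <= res.shift_ability <= 2.0


class TestCallRToS:
    def _res(self, delta):
        return ShiftResult("e", 0.0, delta, delta, False, delta > 0)

    def test_threshold_inclusive(self):
        assert call_r_to_s(self._res(0.7)) is True
        assert call_r_to_s(self._res(0.6999)) is False

    def test_calls_are_suffix_of_sorted_order(self, rng):
        deltas = sorted(rng.uniform(-2, 2, 50))
        calls = [call_r_to_s(self._res(d)) for d in deltas]
        first_true = calls.index(True) if True in calls else len(calls)
        assert all(calls[first_true:])
        assert not any(calls[:first_true])


class TestAssessKnockdown:
    def test_panel_minimum_is_efficient(self):
        genes = ["t", "x"]
        panel = pd.DataFrame(
            [[-3.0, 0.0, 0.5, 1.0], [0, 0, 0, 0]], index=genes,
            columns=["e1", "e2", "e3", "e4"],
        )
        profile = panel["e1"]
        ka = assess_knockdown(profile, "t", panel)
        assert ka.efficient and ka.target_z == -3.0

    def test_positive_target_z_never_efficient(self):
        genes = ["t"]
        panel = pd.DataFrame([[1.0, 5.0, 9.0, 12.0]], index=genes,
                             columns=["e1", "e2", "e3", "e4"])
        ka = assess_knockdown(panel["e1"], "t", panel)
        assert not ka.efficient

    def test_percentile_cut_matches_interpolation_oracle(self, rng):
        vals = rng.normal(0, 1, 8)
        panel = pd.DataFrame([vals], index=["t"], columns=[f"e{i}" for i in range(8)])
        cut = linear_interp_percentile(vals, 25)
        probes = [cut - 0.01, cut + 0.01, cut]
        for probe in probes:
            ka = assess_knockdown(pd.Series({"t": probe}, name="probe"), "t", panel, q=25)
            assert ka.efficient == (probe < 0 and probe <= cut)

    def test_absent_target_has_reason(self):
        panel = pd.DataFrame([[0.0, 1.0]], index=["g"], columns=["e1", "e2"])
        ka = assess_knockdown(panel["e1"], "missing", panel)
        assert not ka.efficient and ka.reason == "target_absent"


class TestAggregatePerturbagen:
    def _results(self, shifts):
        return pd.DataFrame(
            {
                "shift_ability": shifts,
                "perturbagen_id": "c1",
                "cell_line": "A",
                "type": "compound",
                "target": None,
            },
            index=[f"e{i}" for i in range(len(shifts))],
        )

    def test_single_experiment(self):
        out = aggregate_perturbagen(self._results([0.9]))
        row = out.loc[("c1", "A")]
        assert row["mean_shift"] == 0.9 and row["frac_called"] == 1.0 and row["any_call"]

    def test_worked_arithmetic(self):
        out = aggregate_perturbagen(self._results([0.8, 0.6]), threshold=0.7)
        row = out.loc[("c1", "A")]
        assert row["mean_shift"] == pytest.approx(0.7)
        assert row["frac_called"] == pytest.approx(0.5)
        assert bool(row["any_call"])

    def test_order_invariance(self, rng):
        shifts = rng.uniform(-1, 1, 9).tolist()
        a = aggregate_perturbagen(self._results(shifts))
        b = aggregate_perturbagen(self._results(shifts[::-1]))
        assert a.loc[("c1", "A"), "mean_shift"] == pytest.approx(
            b.loc[("c1", "A"), "mean_shift"]
        )


def _screen_frames(sh_rows, cpd_rows):
    sh = pd.DataFrame(sh_rows).set_index("experiment_id")
    cpd = pd.DataFrame(cpd_rows).set_index("experiment_id")
    return sh, cpd


class TestConcordantTargets:
    def _sh_row(self, exp, target, cell, call=True):
        return {
            "experiment_id": exp, "perturbagen_id": f"sh_{target}", "type": "shRNA",
            "target": target, "cell_line": cell, "r_to_s_call": call,
        }

    def _cpd_row(self, exp, pert, cell, call=True):
        return {
            "experiment_id": exp, "perturbagen_id": pert, "type": "compound",
            "target": None, "cell_line": cell, "r_to_s_call": call,
        }

    def test_same_cell_line_required(self):
        sh, cpd = _screen_frames(
            [self._sh_row("s1", "T1", "A")], [self._cpd_row("c1", "drug1", "B")]
        )
        kd = pd.DataFrame({"efficient": [True]}, index=["s1"])
        out = concordant_targets(cpd, sh, kd, {"drug1": ["T1"]})
        assert out == []

    def test_concordant_in_one_cell_line(self):
        sh, cpd = _screen_frames(
            [self._sh_row("s1", "T1", "A")], [self._cpd_row("c1", "drug1", "A")]
        )
        kd = pd.DataFrame({"efficient": [True]}, index=["s1"])
        out = concordant_targets(cpd, sh, kd, {"drug1": ["T1"]})
        assert len(out) == 1
        assert out[0].target_gene == "T1"
        assert out[0].cell_lines_concordant == ["A"]

    def test_inefficient_knockdown_blocks(self):
        sh, cpd = _screen_frames(
            [self._sh_row("s1", "T1", "A")], [self._cpd_row("c1", "drug1", "A")]
        )
        kd = pd.DataFrame({"efficient": [False]}, index=["s1"])
        assert concordant_targets(cpd, sh, kd, {"drug1": ["T1"]}) == []

    def test_unmapped_compound_skipped(self):
        sh, cpd = _screen_frames(
            [self._sh_row("s1", "T1", "A")], [self._cpd_row("c1", "mystery", "A")]
        )
        kd = pd.DataFrame({"efficient": [True]}, index=["s1"])
        assert concordant_targets(cpd, sh, kd, {}) == []


class TestPrioritizeTargets:
    def _assoc(self, rows):
        return pd.DataFrame(rows, columns=["target", "cancer_type", "pearson_r", "pearson_p"])

    def test_no_significant_correlation_not_prioritized(self):
        cands = [TargetPriority("T1", ["A"])]
        assoc = self._assoc([("T1", "ct1", -0.5, 0.2)])
        (out,) = prioritize_targets(cands, assoc)
        assert not out.prioritized and out.n_types_negative == 0

    def test_counting_of_negative_types(self):
        cands = [TargetPriority("T1", ["A"])]
        rows = [("T1", f"ct{i}", -0.5, 0.01) for i in range(3)]
        rows += [("T1", "ct3", -0.1, 0.5), ("T1", "ct4", 0.4, 0.01)]
        (out,) = prioritize_targets(cands, self._assoc(rows), min_types=1)
        assert out.prioritized
        assert out.n_types_negative == 3
        assert out.n_types_positive == 1

    def test_candidate_missing_from_table_excluded(self):
        cands = [TargetPriority("T1", ["A"]), TargetPriority("T2", ["A"])]
        assoc = self._assoc([("T1", "ct1", -0.5, 0.001)])
        out = prioritize_targets(cands, assoc)
        assert [o.target_gene for o in out] == ["T1"]
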