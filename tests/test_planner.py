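"""The staged adjustment loop: rules, priority discipline, rollback, and
the three planning strategies."""

import dataclasses

import numpy as np
import pytest

from autoplan.metrics import (
    EvaluationObjective,
    ObjectiveReport,
    ObjectiveResult,
    evaluate_objectives,
)
from autoplan.optimize import OptimizationConstraint, solve_weights
from autoplan.phantom import PhantomSpec, build_phantom
from autoplan.dose import beam_geometry, influence_matrix
from autoplan.planner import (
    dose_escalation_loop,
    find_failures,
    initial_constraints,
    next_action,
    planning_loop,
)


def fake_report(entries):
    """entries: (id, level, passed) triples in config order."""
    results = []
    for oid, level, passed in entries:
        obj = EvaluationObjective(oid, "s", level, "mean", 10.0, "at_most")
        results.append(ObjectiveResult(obj, 5.0, passed, 1.0))
    results.sort(key=lambda r: r.level)
    return ObjectiveReport(results)


class TestInitialConstraints:
    def test_stage1_targets_only_all_weights_one(
        self, default_phantom, phantom_objectives, phantom_rules
    ):
        cs = initial_constraints(1, default_phantom, phantom_objectives, phantom_rules)
        assert all(c.weight == 1 for c in cs)
        structures = {c.structure for c in cs}
        assert structures <= {"ptv1", "ptv2", "ptv3", "body"}
        assert not any(c.structure.startswith(("cord", "parotid", "rind")) for c in cs)

    def test_stage3_rind_doses_at_95_percent_of_prescription(
        self, default_phantom, phantom_objectives, phantom_rules
    ):
        cs = initial_constraints(3, default_phantom, phantom_objectives, phantom_rules)
        rind = {c.structure: c.dose_gy for c in cs if c.structure.startswith("rind")}
        assert rind["rind1"] == pytest.approx(66.5, abs=0.051)
        assert rind["rind2"] == pytest.approx(59.9, abs=0.051)
        assert rind["rind3"] == pytest.approx(53.2, abs=0.051)
        assert all(c.weight == 1 for c in cs)

    def test_stage_accumulates(self, default_phantom, phantom_objectives, phantom_rules):
        s1 = initial_constraints(1, default_phantom, phantom_objectives, phantom_rules)
        s2 = initial_constraints(2, default_phantom, phantom_objectives, phantom_rules)
        s3 = initial_constraints(3, default_phantom, phantom_objectives, phantom_rules)
        assert {c.id for c in s1} < {c.id for c in s2} < {c.id for c in s3}
        assert any(c.structure == "cord_prv" for c in s2)
        assert any(c.ctype == "max_eud" for c in s3)

    def test_missing_structure_rejected(self, phantom_objectives, phantom_rules):
        tiny = build_phantom(PhantomSpec())
        del tiny.structures["cord_prv"]
        with pytest.raises(KeyError, match="cord_prv"):
            initial_constraints(2, tiny, phantom_objectives, phantom_rules)


class TestFindFailures:
    def test_priority_order(self):
        rep = fake_report([("c3", 3, False), ("a1", 1, False), ("b2", 2, False)])
        ids = [f.id for f in find_failures(rep, 3)]
        assert ids == ["a1", "b2", "c3"]

    def test_stage_filter(self):
        rep = fake_report([("c3", 3, False), ("a1", 1, True)])
        assert [f.id for f in find_failures(rep, 2)] == []
        assert [f.id for f in find_failures(rep, 3)] == ["c3"]

    def test_all_pass_empty(self):
        rep = fake_report([("a1", 1, True), ("b2", 2, True)])
        assert find_failures(rep, 3) == []

    def test_same_level_config_order_preserved(self):
        rep = fake_report([("x", 1, False), ("y", 1, False)])
        assert [f.id for f in find_failures(rep, 1)] == ["x", "y"]


class TestNextAction:
    def _constraints(self, dose=63.0, weight=1, uniform=70.0):
        return [
            OptimizationConstraint(
                "ptv1_min", "ptv1", "min_dose", dose, weight=weight,
                dose_adjustable=True, step_direction="up", dose_ceiling=None,
            ),
            OptimizationConstraint("ptv1_uniform", "ptv1", "uniform_dose", uniform),
        ]

    def test_weight_ladder_progression(self, phantom_rules):
        act = next_action("ptv1_d99", self._constraints(weight=25), phantom_rules)
        assert act.kind == "raise_weight" and act.new_weight == 50

    def test_dose_step_after_ladder_exhausted(self, phantom_rules):
        act = next_action("ptv1_d99", self._constraints(weight=100), phantom_rules)
        assert act.kind == "step_dose_up" and act.new_dose == pytest.approx(64.0)

    def test_conflict_with_uniform_dose(self, phantom_rules):
        act = next_action(
            "ptv1_d99", self._constraints(dose=70.0, weight=100), phantom_rules
        )
        assert act.kind == "no_action"

    def test_step_down_blocked_at_floor(self, phantom_rules):
        cs = [
            OptimizationConstraint(
                "cord_max", "cord_prv", "max_dose", 25.0, weight=100,
                dose_adjustable=True, step_direction="down", dose_floor=25.0,
            )
        ]
        act = next_action("cord_max", cs, phantom_rules)
        assert act.kind == "no_action"

    def test_unmapped_objective_rejected(self, phantom_rules):
        with pytest.raises(KeyError, match="rule"):
            next_action("mystery", self._constraints(), phantom_rules)


class TestStandardStrategy:
    def test_all_objectives_met(self, std_imrt):
        assert std_imrt.feasible
        assert std_imrt.final_report.all_pass()
        assert std_imrt.strategy == "standard" and std_imrt.technique == "imrt7"

    def test_trivial_objectives_need_no_adjustments(
        self, default_phantom, imrt_matrix, phantom_objectives, phantom_rules,
        planner_opts,
    ):
        """Lax thresholds: the loop advances through the stages and finishes
        without a single weight or dose adjustment."""
        lax = []
        for o in phantom_objectives:
            thr = 0.01 if o.direction == "at_least" else 10000.0
            lax.append(dataclasses.replace(o, threshold=thr))
        res = planning_loop(default_phantom, imrt_matrix, lax, phantom_rules,
                            planner_opts)
        assert res.feasible
        kinds = {r["action"]["kind"] for r in res.history if r["action"]}
        assert "raise_weight" not in kinds
        assert "step_dose_up" not in kinds and "step_dose_down" not in kinds

    def test_final_constraints_replay_reproduces_dose(
        self, std_imrt, default_phantom, imrt_matrix, planner_opts
    ):
        plan = solve_weights(
            imrt_matrix, default_phantom, std_imrt.constraints,
            planner_opts.solver, warm_start=std_imrt.final_plan.start_weights,
        )
        assert np.array_equal(plan.dose, std_imrt.final_plan.dose)

    def test_history_is_replayable_record(self, std_imrt):
        recs = std_imrt.history.records
        assert [r["iteration"] for r in recs] == sorted(r["iteration"] for r in recs)
        assert all("constraints" in r and "report" in r for r in recs)


class TestDiscipline:
    """Priority/ladder discipline over the logged histories of real runs."""

    def _histories(self, std_imrt, spare_imrt, esc_imrt):
        return [std_imrt.history, spare_imrt.history, esc_imrt.history]

    def test_higher_priority_failures_worked_first(self, std_imrt, spare_imrt, esc_imrt):
        for history in self._histories(std_imrt, spare_imrt, esc_imrt):
            for rec in history:
                if rec["event"] != "adjust" or not rec["action"]:
                    continue
                acted = rec["action"]["objective_id"]
                levels = {r["id"]: r["level"] for r in rec["report"]}
                failing_levels = [levels[f] for f in rec["failures"]]
                assert levels[acted] == min(failing_levels)

    def test_weight_sequences_follow_ladder(self, std_imrt, spare_imrt, esc_imrt):
        ladder = (1, 10, 25, 50, 75, 100)
        for history in self._histories(std_imrt, spare_imrt, esc_imrt):
            seqs = {}
            for rec in history:
                for cid, st in rec["constraints"].items():
                    seqs.setdefault(cid, []).append(st["weight"])
            for cid, seq in seqs.items():
                dedup = [seq[0]] + [w for a, w in zip(seq, seq[1:]) if w != a]
                assert all(w in ladder for w in dedup)
                assert all(
                    ladder.index(a) < ladder.index(b) for a, b in zip(dedup, dedup[1:])
                )

    def test_dose_steps_only_at_max_weight(self, std_imrt, spare_imrt, esc_imrt):
        for history in self._histories(std_imrt, spare_imrt, esc_imrt):
            for rec in history:
                a = rec["action"]
                if a and a["kind"] in ("step_dose_up", "step_dose_down"):
                    assert rec["constraints"][a["constraint_id"]]["weight"] == 100

    def test_rollback_restores_all_pass_state(
        self, spare_imrt, default_phantom, phantom_objectives
    ):
        assert spare_imrt.stop_reason in ("rolled_back", "complete", "iteration_cap")
        rep = evaluate_objectives(
            spare_imrt.final_plan.dose, default_phantom, spare_imrt.objectives
        )
        assert rep.all_pass()
        # the live constraint set is the snapshot the planner rolled back to
        from autoplan.optimize import constraint_state_hash

        assert (
            constraint_state_hash(spare_imrt.constraints)
            == spare_imrt.final_plan.constraint_hash
        )


class TestSparingStrategy:
    def test_reported_minimum_is_last_snapshot_mean(self, spare_imrt, default_phantom):
        union = default_phantom.flat_mask("parotid_l") | default_phantom.flat_mask(
            "parotid_r"
        )
        assert spare_imrt.spared_min_mean == pytest.approx(
            float(spare_imrt.final_plan.dose[union].mean())
        )

    def test_minimum_not_above_base_plan(self, std_imrt, spare_imrt, default_phantom):
        union = default_phantom.flat_mask("parotid_l") | default_phantom.flat_mask(
            "parotid_r"
        )
        base = float(std_imrt.final_plan.dose[union].mean())
        assert spare_imrt.spared_min_mean <= base + 1e-9

    def test_accepted_means_nonincreasing(self, spare_imrt):
        trace = spare_imrt.spared_mean_trace
        assert len(trace) >= 1
        assert all(a >= b - 1e-9 for a, b in zip(trace, trace[1:]))

    def test_arc_spares_at_least_as_well_on_asymmetric_phantom(
        self, asym_phantom, phantom_objectives, phantom_rules, planner_opts
    ):
        """More angular freedom cannot spare the parotids less."""
        from autoplan.planner import oar_sparing_loop

        means = {}
        for tech, sp in (("imrt7", 10.0), ("arc", 10.0)):
            basis = beam_geometry(tech, asym_phantom, spacing_deg=sp)
            mat = influence_matrix(basis, asym_phantom)
            res = oar_sparing_loop(
                asym_phantom, mat, phantom_objectives, phantom_rules, "parotids",
                planner_opts,
            )
            means[tech] = res.spared_min_mean
        assert means["arc"] <= means["imrt7"] + 1e-9

    def test_unknown_spared_oar_rejected(
        self, default_phantom, imrt_matrix, phantom_objectives, phantom_rules,
        planner_opts,
    ):
        from autoplan.planner import oar_sparing_loop

        with pytest.raises(KeyError, match="spared"):
            oar_sparing_loop(
                default_phantom, imrt_matrix, phantom_objectives, phantom_rules,
                "larynx", planner_opts,
            )


class TestEscalationStrategy:
    def test_limit_on_2gy_grid_with_named_objective(self, esc_imrt, esc_arc):
        for res in (esc_imrt, esc_arc):
            k = (res.limiting_prescription - 70.0) / 2.0
            assert k == int(k) and k >= 0
            if res.stop_reason in ("rolled_back", "iteration_cap"):
                assert res.limiting_objective in {o.id for o in res.objectives}

    def test_final_state_passes_at_limiting_prescription(
        self, esc_imrt, default_phantom
    ):
        rep = evaluate_objectives(
            esc_imrt.final_plan.dose, default_phantom, esc_imrt.objectives
        )
        assert rep.all_pass()
        # the restored threshold context matches the limiting prescription
        d95 = next(o for o in esc_imrt.objectives if o.id == "ptv1_d95")
        assert d95.threshold == pytest.approx(
            0.95 * esc_imrt.limiting_prescription, rel=1e-3
        )

    def test_prescription_trace_steps_by_two(self, esc_imrt):
        trace = esc_imrt.prescription_trace
        assert trace[0] == 70.0
        assert all(b - a == pytest.approx(2.0) for a, b in zip(trace, trace[1:]))
        assert esc_imrt.limiting_prescription == trace[-1]

    def test_limit_monotone_in_oar_gap(
        self, phantom_objectives, phantom_rules, planner_opts
    ):
        """Moving the serial OAR closer to the target never raises the limit."""
        limits = []
        for cord_y in (-17.0, -20.0, -26.0):
            ph = build_phantom(PhantomSpec(serial_oar_center_mm=(0.0, cord_y)))
            mat = influence_matrix(beam_geometry("imrt7", ph), ph)
            res = dose_escalation_loop(ph, mat, phantom_objectives, phantom_rules,
                                       planner_opts)
            limits.append(res.limiting_prescription)
        assert limits[0] <= limits[1] <= limits[2]
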