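"""The automated inverse-planning loop.

This is the heart of the package: a staged, rule-driven cycle that emulates
an experienced planner operating an inverse treatment planning system
without human input, so that two delivery techniques can be compared free
of planner bias.

The cycle (per iteration): solve the fluence optimization for the live
constraint set, evaluate the clinical objectives, and then either

* fix the highest-priority failing objective by applying the next permitted
  adjustment from a predefined rule set -- first climbing the penalty-weight
  ladder (1, 10, 25, 50, 75, 100), then stepping the constraint dose in
  1 Gy increments (up for coverage, down for sparing constraints) -- or
* when everything passes, take a snapshot (the rollback point) and apply
  the strategy's progress move: tighten the rind (dummy shell) constraints
  for standard planning, lower the spared-OAR constraint for the sparing
  strategy, or raise the prescription by 2 Gy for isotoxic escalation.

Constraints are introduced in three priority stages: targets plus the
global maximum first, then serial organs at risk, then parallel OARs and
the rind shells.  Higher-priority failures are always worked on first.
When no permitted adjustment remains for a failing objective (for example
a coverage constraint dose would conflict with the same structure's uniform
dose constraint), the planner rolls back to the last all-pass snapshot and
stops: a plan is only complete if every objective is met.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, replace

import numpy as np

from .dose import InfluenceMatrix
from .metrics import (
    EvaluationObjective,
    ObjectiveReport,
    ObjectiveResult,
    evaluate_objectives,
)
from .optimize import (
    WEIGHT_LADDER,
    OptimizationConstraint,
    Plan,
    SolverOptions,
    constraint_state_hash,
    solve_weights,
)
from .phantom import Phantom

ACTION_KINDS = ("raise_weight", "step_dose_up", "step_dose_down", "tighten_rind", "no_action")


@dataclass
class AdjustmentAction:
    """A single permitted modification of the live constraint set."""

    kind: str
    constraint_id: str | None = None
    objective_id: str | None = None
    new_weight: int | None = None
    new_dose: float | None = None
    step_gy: float = 1.0

    def __post_init__(self):
        if self.kind not in ACTION_KINDS:
            raise ValueError(f"unknown action kind {self.kind!r}")
        if self.kind in ("step_dose_up", "step_dose_down") and self.step_gy <= 0:
            raise ValueError("dose steps require step_gy > 0")


# ---------------------------------------------------------------------------
# rule set: the machine-readable "initialization file"


@dataclass
class DoseSpec:
    """A constraint dose given either absolutely or as a prescription fraction."""

    value: float | None = None
    fraction: float | None = None
    of: str | None = None  # 'rx1' | 'rx2' | 'rx3'

    def resolve(self, prescriptions: tuple[float, float, float]) -> float:
        if self.value is not None:
            return float(self.value)
        idx = {"rx1": 0, "rx2": 1, "rx3": 2}[self.of]
        return self.fraction * prescriptions[idx]

    @property
    def rx_linked(self) -> str | None:
        return self.of if self.value is None else None


@dataclass
class ConstraintTemplate:
    """Blueprint for one optimization constraint in the rules config."""

    id: str
    structure: str
    ctype: str
    stage: int
    dose: DoseSpec
    volume_pct: float | None = None
    eud_a: float = 1.0
    weight_adjustable: bool = True
    dose_adjustable: bool = False
    step_direction: str | None = None
    dose_floor: DoseSpec = field(default_factory=lambda: DoseSpec(value=1.0))
    dose_ceiling: DoseSpec | None = None

    def instantiate(self, prescriptions) -> OptimizationConstraint:
        return OptimizationConstraint(
            id=self.id,
            structure=self.structure,
            ctype=self.ctype,
            dose_gy=self.dose.resolve(prescriptions),
            weight=1,
            volume_pct=self.volume_pct,
            eud_a=self.eud_a,
            stage=self.stage,
            weight_adjustable=self.weight_adjustable,
            dose_adjustable=self.dose_adjustable,
            step_direction=self.step_direction,
            dose_floor=self.dose_floor.resolve(prescriptions),
            dose_ceiling=(
                self.dose_ceiling.resolve(prescriptions) if self.dose_ceiling else None
            ),
        )


@dataclass
class RuleEntry:
    """Constraints (in order) and permitted action kinds for one objective."""

    constraint_ids: list[str]
    actions: tuple[str, ...] = ("raise_weight", "step_dose_up", "step_dose_down")


@dataclass
class RuleSet:
    """The full predefined rule set driving the automated planner."""

    templates: list[ConstraintTemplate]
    rules: dict[str, RuleEntry]
    ladder: tuple[int, ...] = WEIGHT_LADDER
    step_gy: float = 1.0
    rind_tighten_factor: float = 0.98
    rind_floor_fraction: float = 0.90
    sparing_step_gy: float = 1.0

    def __post_init__(self):
        if tuple(sorted(set(self.ladder))) != tuple(self.ladder) or self.ladder[-1] != 100:
            raise ValueError("weight ladder must be strictly increasing and end at 100")
        known = {t.id for t in self.templates}
        for oid, entry in self.rules.items():
            missing = [cid for cid in entry.constraint_ids if cid not in known]
            if missing:
                raise ValueError(
                    f"rule for objective {oid!r} references unknown constraint ids {missing}"
                )

    def validate_against(self, objectives: list[EvaluationObjective]) -> None:
        unmapped = [o.id for o in objectives if o.id not in self.rules]
        if unmapped:
            raise ValueError(f"objectives with no adjustment rule: {unmapped}")

    def template_by_id(self, cid: str) -> ConstraintTemplate:
        for t in self.templates:
            if t.id == cid:
                return t
        raise KeyError(cid)


# ---------------------------------------------------------------------------
# planner state and history


@dataclass
class PlannerOptions:
    max_planner_iterations: int = 150
    solver: SolverOptions = field(default_factory=SolverOptions)
    warm_start: bool = True
    escalation_step_gy: float = 2.0
    escalation_cap_gy: float = 130.0
    #: spared-constraint weight is raised (instead of the dose lowered) while
    #: the achieved mean sits this far above the constraint dose
    sparing_weight_slack_gy: float = 0.5


@dataclass
class Snapshot:
    constraints: list[OptimizationConstraint]
    plan: Plan
    report: ObjectiveReport
    prescription: float | None = None
    spared_mean: float | None = None


class PlannerHistory:
    """Append-only, replayable record of every planner iteration."""

    def __init__(self):
        self.records: list[dict] = []

    def append(self, **record) -> None:
        self.records.append(record)

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec) + "\n")


@dataclass
class StrategyResult:
    strategy: str
    technique: str
    feasible: bool
    stop_reason: str
    final_plan: Plan | None
    final_report: ObjectiveReport | None
    constraints: list[OptimizationConstraint]
    history: PlannerHistory
    objectives: list[EvaluationObjective]
    spared_min_mean: float | None = None
    spared_mean_trace: list[float] | None = None
    limiting_prescription: float | None = None
    limiting_objective: str | None = None
    prescription_trace: list[float] | None = None


# ---------------------------------------------------------------------------
# rule application primitives


def initial_constraints(
    stage: int,
    phantom: Phantom,
    objectives: list[EvaluationObjective],
    rules: RuleSet,
) -> list[OptimizationConstraint]:
    """Instantiate the cumulative constraint set for a priority stage.

    Stage 1 holds target coverage/uniformity plus the whole-body maximum;
    stage 2 adds serial-OAR maximum doses; stage 3 adds parallel-OAR gEUD
    constraints and the three rind shells at 95% of each PTV prescription.
    All weights start at 1.
    """
    if stage not in (1, 2, 3):
        raise ValueError("stage must be 1, 2 or 3")
    rules.validate_against(objectives)
    out = []
    for t in rules.templates:
        if t.stage <= stage:
            if t.structure not in phantom:
                raise KeyError(
                    f"constraint {t.id!r} references unknown structure {t.structure!r}"
                )
            out.append(t.instantiate(phantom.prescriptions_gy))
    return out


def find_failures(report: ObjectiveReport, stage: int) -> list[ObjectiveResult]:
    """Failing objectives at levels <= stage, highest priority first.

    The report is already ordered by (level, config order), so the filtered
    list preserves that discipline.
    """
    return report.failures(max_level=stage)


def _next_ladder_weight(ladder: tuple[int, ...], current: int) -> int | None:
    for v in ladder:
        if v > current:
            return v
    return None


def _step_bound_up(c: OptimizationConstraint, constraints: list[OptimizationConstraint]) -> float:
    """Largest dose a coverage constraint may reach without conflicting."""
    bound = c.dose_ceiling if c.dose_ceiling is not None else np.inf
    for other in constraints:
        if other.id != c.id and other.structure == c.structure and other.ctype in (
            "uniform_dose",
            "max_dose",
        ):
            bound = min(bound, other.dose_gy)
    return bound


def next_action(
    objective_id: str,
    constraints: list[OptimizationConstraint],
    rules: RuleSet,
    step_gy: float | None = None,
) -> AdjustmentAction:
    """The next permitted adjustment for a failing objective.

    Weight ladder first across all associated constraints; once a
    constraint's weight is maxed, its dose may step (1 Gy default) -- up for
    coverage constraints, bounded by the same structure's uniform/maximum
    dose (the conflict rule), down for sparing constraints, bounded by the
    configured floor.  If nothing is permitted the objective has
    irreversibly failed and ``no_action`` is returned.
    """
    if objective_id not in rules.rules:
        raise KeyError(f"no adjustment rule for objective {objective_id!r}")
    entry = rules.rules[objective_id]
    step = step_gy if step_gy is not None else rules.step_gy
    by_id = {c.id: c for c in constraints}
    live = [by_id[cid] for cid in entry.constraint_ids if cid in by_id]
    if "raise_weight" in entry.actions:
        for c in live:
            if c.weight_adjustable and c.weight < rules.ladder[-1]:
                return AdjustmentAction(
                    kind="raise_weight",
                    constraint_id=c.id,
                    objective_id=objective_id,
                    new_weight=_next_ladder_weight(rules.ladder, c.weight),
                )
    for c in live:
        if not c.dose_adjustable:
            continue
        if c.step_direction == "up" and "step_dose_up" in entry.actions:
            proposed = c.dose_gy + step
            if proposed <= _step_bound_up(c, constraints) + 1e-9:
                return AdjustmentAction(
                    kind="step_dose_up",
                    constraint_id=c.id,
                    objective_id=objective_id,
                    new_dose=proposed,
                    step_gy=step,
                )
        elif c.step_direction == "down" and "step_dose_down" in entry.actions:
            proposed = c.dose_gy - step
            if proposed >= c.dose_floor - 1e-9:
                return AdjustmentAction(
                    kind="step_dose_down",
                    constraint_id=c.id,
                    objective_id=objective_id,
                    new_dose=proposed,
                    step_gy=step,
                )
    return AdjustmentAction(kind="no_action", objective_id=objective_id)


def _apply_action(action: AdjustmentAction, constraints: list[OptimizationConstraint]) -> None:
    c = next(c for c in constraints if c.id == action.constraint_id)
    if action.kind == "raise_weight":
        c.weight = action.new_weight
    elif action.kind in ("step_dose_up", "step_dose_down"):
        c.dose_gy = action.new_dose
    else:  # pragma: no cover
        raise ValueError(f"cannot apply action kind {action.kind!r}")


def _tighten_rinds(constraints: list[OptimizationConstraint], rules: RuleSet) -> list[str]:
    """Group action: shrink every rind constraint dose toward its floor.

    Applied only when all objectives pass.  Returns the ids actually
    tightened (empty when every rind already sits at its floor).
    """
    changed = []
    for c in constraints:
        if c.structure.startswith("rind") and c.ctype == "max_dose":
            new = max(c.dose_gy * rules.rind_tighten_factor, c.dose_floor)
            if new < c.dose_gy - 1e-9:
                c.dose_gy = new
                changed.append(c.id)
    return changed


# ---------------------------------------------------------------------------
# the loop engine


class _LoopContext:
    def __init__(self, phantom, matrix, objectives, rules, opts, strategy):
        self.phantom = phantom
        self.matrix = matrix
        self.objectives = [replace(o) for o in objectives]
        self.rules = rules
        self.opts = opts
        self.strategy = strategy
        self.stage = 1
        self.constraints = initial_constraints(1, phantom, self.objectives, rules)
        self.snapshot: Snapshot | None = None
        self.history = PlannerHistory()
        self.iteration = 0
        self.warm: np.ndarray | None = None
        self.prescriptions = list(phantom.prescriptions_gy)
        self.spared_cids: list[str] = []
        self.spared_masks: np.ndarray | None = None
        self.best_spared_mean: float | None = None
        self.spared_trace: list[float] = []
        self.rx_trace: list[float] = []
        self.blocked_objective: str | None = None

    # -- helpers -------------------------------------------------------

    def solve(self) -> Plan:
        warm = self.warm if self.opts.warm_start else None
        plan = solve_weights(
            self.matrix, self.phantom, self.constraints, self.opts.solver, warm_start=warm
        )
        self.warm = plan.weights
        return plan

    def evaluate(self, plan: Plan) -> ObjectiveReport:
        return evaluate_objectives(plan.dose, self.phantom, self.objectives)

    def take_snapshot(self, plan, report, **extras) -> None:
        self.snapshot = Snapshot(
            constraints=copy.deepcopy(self.constraints),
            plan=plan,
            report=report,
            **extras,
        )

    def record(self, event, plan, report, action=None, failures=()):
        self.history.append(
            iteration=self.iteration,
            stage=self.stage,
            event=event,
            action=None
            if action is None
            else {
                "kind": action.kind,
                "constraint_id": action.constraint_id,
                "objective_id": action.objective_id,
                "new_weight": action.new_weight,
                "new_dose": action.new_dose,
            },
            all_pass=report.all_pass(self.stage),
            failures=[f.id for f in failures],
            report=[
                {"id": r.id, "level": r.level, "achieved": round(r.achieved, 4), "passed": r.passed}
                for r in report.results
            ],
            constraints={c.id: {"dose_gy": round(c.dose_gy, 4), "weight": c.weight}
                         for c in self.constraints},
            constraint_hash=constraint_state_hash(self.constraints),
            objective_value=plan.objective_value,
        )

    def advance_stage(self) -> None:
        self.stage += 1
        have = {c.id for c in self.constraints}
        for t in self.rules.templates:
            if t.stage == self.stage and t.id not in have:
                if t.structure not in self.phantom:
                    raise KeyError(
                        f"constraint {t.id!r} references unknown structure {t.structure!r}"
                    )
                self.constraints.append(t.instantiate(tuple(self.prescriptions)))


def _run_loop(ctx: _LoopContext, on_all_pass) -> str:
    """Shared solve/evaluate/adjust cycle.

    ``on_all_pass(ctx, plan, report) -> str`` performs the strategy's
    progress move once every objective passes at full stage; it returns the
    event label, or ``'complete'`` to finish.  Returns the stop reason.
    """
    opts = ctx.opts
    while ctx.iteration < opts.max_planner_iterations:
        plan = ctx.solve()
        report = ctx.evaluate(plan)
        failures = find_failures(report, ctx.stage)
        if failures:
            action = next_action(failures[0].id, ctx.constraints, ctx.rules)
            ctx.record("adjust", plan, report, action=action, failures=failures)
            if action.kind == "no_action":
                ctx.blocked_objective = failures[0].id
                return "blocked"
            _apply_action(action, ctx.constraints)
        elif ctx.stage < 3:
            ctx.record("advance_stage", plan, report)
            ctx.advance_stage()
        else:
            event = on_all_pass(ctx, plan, report)
            ctx.record(event, plan, report)
            if event == "complete":
                return "complete"
        ctx.iteration += 1
    return "iteration_cap"


def _finish(ctx: _LoopContext, strategy: str, stop: str, **extras) -> StrategyResult:
    if stop in ("blocked", "iteration_cap") and ctx.snapshot is not None:
        ctx.constraints = copy.deepcopy(ctx.snapshot.constraints)
        plan, report = ctx.snapshot.plan, ctx.snapshot.report
        stop = "rolled_back" if stop == "blocked" else stop
        feasible = True
    elif stop == "complete":
        plan = ctx.snapshot.plan if ctx.snapshot else None
        report = ctx.snapshot.report if ctx.snapshot else None
        feasible = ctx.snapshot is not None
    else:
        plan = report = None
        feasible = False
        stop = "infeasible"
    return StrategyResult(
        strategy=strategy,
        technique=ctx.matrix.basis.technique,
        feasible=feasible,
        stop_reason=stop,
        final_plan=plan,
        final_report=report,
        constraints=ctx.constraints,
        history=ctx.history,
        objectives=ctx.objectives,
        **extras,
    )


# ---------------------------------------------------------------------------
# strategies


def planning_loop(
    phantom: Phantom,
    matrix: InfluenceMatrix,
    objectives: list[EvaluationObjective],
    rules: RuleSet,
    opts: PlannerOptions = None,
) -> StrategyResult:
    """Standard strategy: reach an all-pass plan, then tighten the rinds.

    Stages are introduced 1 -> 1+2 -> 1+2+3; every all-pass state is
    snapshotted; the rind (dummy shell) group action tightens conformity
    while possible; the loop ends by completion (rinds at their floor) or
    by rollback to the last snapshot once an objective irreversibly fails.
    """
    opts = opts or PlannerOptions()
    ctx = _LoopContext(phantom, matrix, objectives, rules, opts, "standard")

    def on_pass(ctx, plan, report):
        ctx.take_snapshot(plan, report)
        changed = _tighten_rinds(ctx.constraints, ctx.rules)
        return "tighten_rind" if changed else "complete"

    stop = _run_loop(ctx, on_pass)
    return _finish(ctx, "standard", stop)


def _resolve_spared(phantom: Phantom, rules: RuleSet, spared_oar: str):
    """Structures and gEUD constraint ids targeted by the sparing strategy."""
    names = [
        s.name
        for s in phantom.by_role("parallel_oar")
        if s.name == spared_oar or s.name.startswith(spared_oar.rstrip("s"))
    ]
    if not names:
        raise KeyError(f"no parallel OAR matches spared label {spared_oar!r}")
    cids = [
        t.id
        for t in rules.templates
        if t.structure in names and t.ctype == "max_eud"
    ]
    if not cids:
        raise ValueError(f"no gEUD constraint found for spared OAR {spared_oar!r}")
    return names, cids


def oar_sparing_loop(
    phantom: Phantom,
    matrix: InfluenceMatrix,
    objectives: list[EvaluationObjective],
    rules: RuleSet,
    spared_oar: str,
    opts: PlannerOptions = None,
) -> StrategyResult:
    """Sparing strategy: push the spared OAR's mean dose as low as possible.

    After a standard all-pass plan is reached, the spared OAR's gEUD
    constraint dose is lowered in 1 Gy steps (with the weight ladder
    available while the achieved mean lags the constraint); every recovered
    all-pass state with a no-worse spared mean becomes the new rollback
    point.  Other level-3 OARs are left at their tolerances (their stricter
    aspiration targets, once met, take them out of play).  The loop ends by
    rollback on an irreversible higher-level failure, by the constraint
    floor, or at the iteration cap; the reported minimum is the spared mean
    of the last accepted snapshot.
    """
    opts = opts or PlannerOptions()
    ctx = _LoopContext(phantom, matrix, objectives, rules, opts, "spare")
    names, cids = _resolve_spared(phantom, rules, spared_oar)
    ctx.spared_cids = cids
    union = np.zeros(phantom.grid.size, dtype=bool)
    for n in names:
        union |= phantom.flat_mask(n)
    ctx.spared_masks = union
    by_name = {n: phantom.flat_mask(n) for n in names}
    cid_struct = {t.id: t.structure for t in rules.templates}

    def spared_mean(plan):
        return float(plan.dose[union].mean())

    def on_pass(ctx, plan, report):
        mean = spared_mean(plan)
        if ctx.best_spared_mean is None or mean <= ctx.best_spared_mean + 1e-9:
            ctx.best_spared_mean = mean if ctx.best_spared_mean is None else min(
                ctx.best_spared_mean, mean
            )
            ctx.take_snapshot(plan, report, spared_mean=ctx.best_spared_mean)
            ctx.spared_trace.append(ctx.best_spared_mean)
        live = {c.id: c for c in ctx.constraints}
        # ladder first while the achieved mean lags the constraint dose
        for cid in cids:
            c = live[cid]
            ach = float(plan.dose[by_name[cid_struct[cid]]].mean())
            if (
                c.weight < ctx.rules.ladder[-1]
                and ach > c.dose_gy + ctx.opts.sparing_weight_slack_gy
            ):
                c.weight = _next_ladder_weight(ctx.rules.ladder, c.weight)
                return "spare_raise_weight"
        stepped = False
        for cid in cids:
            c = live[cid]
            new = c.dose_gy - ctx.rules.sparing_step_gy
            if new >= c.dose_floor - 1e-9:
                c.dose_gy = new
                stepped = True
        return "spare_step_down" if stepped else "complete"

    stop = _run_loop(ctx, on_pass)
    if ctx.snapshot is None:
        raise RuntimeError("sparing strategy requires a feasible base plan")
    return _finish(
        ctx,
        "spare",
        stop,
        spared_min_mean=ctx.snapshot.spared_mean,
        spared_mean_trace=ctx.spared_trace,
    )


def _rescale_rx1(ctx: _LoopContext, new_rx1: float) -> None:
    """Represcribe the primary target: scale every rx1-linked quantity.

    Objective thresholds on the primary PTV and the whole-body maximum, the
    PTV1-linked constraint doses (including the PTV1 rind and the global
    maximum), and their floors/ceilings all scale by the prescription
    ratio; the lower dose levels stay fixed.
    """
    ratio = new_rx1 / ctx.prescriptions[0]
    ctx.prescriptions[0] = new_rx1
    for obj in ctx.objectives:
        if obj.structure == "ptv1" or (obj.structure == "body" and obj.metric == "max"):
            obj.threshold *= ratio
    for c in ctx.constraints:
        t = ctx.rules.template_by_id(c.id)
        if t.dose.rx_linked == "rx1":
            c.dose_gy *= ratio
            c.dose_floor = t.dose_floor.resolve(tuple(ctx.prescriptions))
            if t.dose_ceiling is not None:
                c.dose_ceiling = t.dose_ceiling.resolve(tuple(ctx.prescriptions))


def dose_escalation_loop(
    phantom: Phantom,
    matrix: InfluenceMatrix,
    objectives: list[EvaluationObjective],
    rules: RuleSet,
    opts: PlannerOptions = None,
) -> StrategyResult:
    """Isotoxic escalation: raise the primary prescription in 2 Gy steps.

    From an all-pass plan at the base prescription, the primary target
    prescription is escalated by 2 Gy at a time; each step rescales the
    primary PTV coverage thresholds (95%/90% of the new prescription), the
    PTV1-linked constraint doses, the PTV1 rind and the whole-body maximum
    (110% of prescription), leaving the lower dose levels fixed; the
    adjustment loop then runs to recover an all-pass state.  On an
    irreversible failure the planner rolls back; the result reports the
    last all-pass prescription and the objective that blocked the next step.
    """
    opts = opts or PlannerOptions()
    ctx = _LoopContext(phantom, matrix, objectives, rules, opts, "escalate")

    def on_pass(ctx, plan, report):
        rx = ctx.prescriptions[0]
        ctx.take_snapshot(plan, report, prescription=rx)
        ctx.rx_trace.append(rx)
        new_rx = rx + ctx.opts.escalation_step_gy
        if new_rx > ctx.opts.escalation_cap_gy:
            return "complete"
        _rescale_rx1(ctx, new_rx)
        return "escalate"

    stop = _run_loop(ctx, on_pass)
    if ctx.snapshot is None:
        raise RuntimeError("escalation strategy requires a feasible base plan")
    if ctx.snapshot.prescription is None:
        raise RuntimeError("escalation never reached an all-pass prescription")
    if ctx.prescriptions[0] != ctx.snapshot.prescription:
        # roll the prescription context back alongside the constraints
        _rescale_rx1(ctx, ctx.snapshot.prescription)
    result = _finish(
        ctx,
        "escalate",
        stop,
        limiting_prescription=ctx.snapshot.prescription,
        limiting_objective=ctx.blocked_objective,
        prescription_trace=ctx.rx_trace,
    )
    return result
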