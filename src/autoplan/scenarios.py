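"""Synthetic study cohorts: paired technique runs over jittered phantoms.

Emulates the design of a ten-patient paired planning study: each case is a
deterministic geometric variation of the default phantom (target sizes,
nodal and parotid placement, unilateral vs bilateral nodal disease in a
fixed alternating half/half mix), and every strategy is run with both the
fixed-field and the rotational beamlet basis under identical objectives and
rules, yielding a :class:`~autoplan.stats.PairedSample` for the
signed-rank comparison.

Desk scale: single-slice phantoms on a 2.5 mm grid with a 10-degree arc
control-point spacing (36 directions, ~900 beamlets) so a full cohort of
paired runs stays within minutes on one CPU.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .configio import load_objectives, load_rules, packaged_path
from .dose import KernelParams, beam_geometry, influence_matrix
from .phantom import PhantomSpec, build_phantom
from .planner import (
    PlannerOptions,
    StrategyResult,
    dose_escalation_loop,
    oar_sparing_loop,
    planning_loop,
)
from .optimize import SolverOptions
from .stats import PairedSample

log = logging.getLogger(__name__)

STRATEGIES = ("standard", "spare", "escalate")

#: desk-scale arc control-point spacing (degrees) used by the cohort runs
COHORT_ARC_SPACING_DEG = 10.0


def cohort_planner_options() -> PlannerOptions:
    """Planner settings used for cohort runs (solver budget kept modest)."""
    return PlannerOptions(
        max_planner_iterations=150,
        solver=SolverOptions(max_iterations=60, tol=1e-5, max_outer_rounds=6),
        warm_start=True,
    )


@dataclass
class Scenario:
    """One synthetic case: a phantom spec plus run configuration."""

    name: str
    spec: PhantomSpec
    objectives_id: str = "objectives_phantom"
    rules_id: str = "rules_phantom"
    techniques: tuple[str, ...] = ("imrt7", "arc")
    strategy: str = "standard"
    arc_spacing_deg: float = COHORT_ARC_SPACING_DEG
    seed: int = 0


def default_cohort(n_cases: int = 10, seed: int = 0) -> list[Scenario]:
    """Deterministic jittered cohort mirroring a ten-patient study design.

    Geometry jitter (target radius, nodal/parotid placement, OAR gap) is
    drawn from a generator seeded by ``seed``; laterality alternates
    unilateral/bilateral so a default cohort splits half and half.  Jitter
    ranges are small enough that the standard strategy remains feasible for
    every default case.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    rng = np.random.default_rng(seed)
    base = PhantomSpec()
    out = []
    for i in range(n_cases):
        jitter = rng.uniform(-1.0, 1.0, size=7)
        spec = replace(
            base,
            ctv1_radius_mm=base.ctv1_radius_mm + 2.0 * jitter[0],
            node2_radius_mm=base.node2_radius_mm + 1.5 * jitter[1],
            node3_radius_mm=base.node3_radius_mm + 1.5 * jitter[2],
            node2_offset_mm=(
                base.node2_offset_mm[0] + 2.0 * jitter[3],
                base.node2_offset_mm[1],
            ),
            node3_offset_mm=(
                base.node3_offset_mm[0] + 2.0 * jitter[4],
                base.node3_offset_mm[1],
            ),
            parotid_offset_mm=(
                base.parotid_offset_mm[0] + 2.0 * jitter[5],
                base.parotid_offset_mm[1],
            ),
            serial_oar_center_mm=(
                base.serial_oar_center_mm[0],
                base.serial_oar_center_mm[1] + 1.5 * jitter[6],
            ),
            laterality="unilateral" if i % 2 == 0 else "bilateral",
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        out.append(Scenario(name=f"case{i + 1:02d}", spec=spec, seed=spec.seed))
    return out


def run_scenario(
    scenario: Scenario,
    strategy: str,
    technique: str,
    spared_oar: str = "parotids",
    opts: PlannerOptions | None = None,
    cache: dict | None = None,
) -> StrategyResult:
    """Run one strategy for one case and technique.

    ``cache`` (optional dict) reuses phantoms and influence matrices across
    strategies for the same case/technique.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    opts = opts or cohort_planner_options()
    key = (scenario.name, "phantom")
    if cache is not None and key in cache:
        phantom = cache[key]
    else:
        phantom = build_phantom(scenario.spec)
        if cache is not None:
            cache[key] = phantom
    mkey = (scenario.name, technique)
    if cache is not None and mkey in cache:
        matrix = cache[mkey]
    else:
        basis = beam_geometry(
            technique, phantom, spacing_deg=scenario.arc_spacing_deg
        )
        matrix = influence_matrix(basis, phantom, KernelParams())
        if cache is not None:
            cache[mkey] = matrix
    objectives = load_objectives(packaged_path(scenario.objectives_id))
    rules = load_rules(packaged_path(scenario.rules_id), objectives)
    if strategy == "standard":
        return planning_loop(phantom, matrix, objectives, rules, opts)
    if strategy == "spare":
        return oar_sparing_loop(phantom, matrix, objectives, rules, spared_oar, opts)
    return dose_escalation_loop(phantom, matrix, objectives, rules, opts)


@dataclass
class CohortResult:
    strategy: str
    pairs: PairedSample | None
    results: dict[str, dict[str, StrategyResult]] = field(default_factory=dict)
    excluded: list[str] = field(default_factory=list)


def _pair_value(result: StrategyResult, strategy: str, phantom_mask) -> float:
    if strategy == "spare":
        return float(result.spared_min_mean)
    if strategy == "escalate":
        return float(result.limiting_prescription)
    # standard: the achieved parotid mean, the quantity the techniques are
    # expected to differ on
    return float(result.final_plan.dose[phantom_mask].mean())


def run_cohort(
    scenarios: list[Scenario],
    strategy: str,
    techniques: tuple[str, str] = ("imrt7", "arc"),
    spared_oar: str = "parotids",
    opts: PlannerOptions | None = None,
    cache: dict | None = None,
) -> CohortResult:
    """Run a strategy over the cohort with both techniques, pairing results.

    Objectives and rules are identical for both techniques.  Cases where
    either technique is infeasible are recorded and excluded from the
    paired sample with a warning.
    """
    results: dict[str, dict[str, StrategyResult]] = {}
    labels, a_vals, b_vals, subgroups = [], [], [], []
    excluded = []
    own_cache = cache if cache is not None else {}
    for sc in scenarios:
        per_tech = {}
        for tech in techniques:
            per_tech[tech] = run_scenario(
                sc, strategy, tech, spared_oar=spared_oar, opts=opts, cache=own_cache
            )
        results[sc.name] = per_tech
        if not all(r.feasible for r in per_tech.values()):
            log.warning("case %s infeasible under %s; excluded from pairing",
                        sc.name, strategy)
            excluded.append(sc.name)
            continue
        phantom = own_cache[(sc.name, "phantom")]
        union = phantom.flat_mask("parotid_l") | phantom.flat_mask("parotid_r")
        labels.append(sc.name)
        a_vals.append(_pair_value(per_tech[techniques[0]], strategy, union))
        b_vals.append(_pair_value(per_tech[techniques[1]], strategy, union))
        subgroups.append(sc.spec.laterality)
    pairs = (
        PairedSample(labels, np.array(a_vals), np.array(b_vals), subgroups)
        if labels
        else None
    )
    return CohortResult(strategy=strategy, pairs=pairs, results=results, excluded=excluded)
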