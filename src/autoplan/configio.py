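"""Config parsing, validation and run artifacts.

Human-readable YAML configs tie the pipeline together: an evaluation-
objectives file (the clinical protocol), a rules file (the planner's
predefined "initialization file": constraint templates, objective-to-
constraint mapping, weight ladder and step sizes), and a phantom spec.
Doses are total Gy throughout; the fraction count is bookkeeping only and
never enters a computation.

Schema violations raise ``ConfigError`` naming the offending file, entry
and field.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .metrics import EvaluationObjective, cumulative_dvh
from .phantom import Phantom, PhantomSpec
from .planner import (
    ConstraintTemplate,
    DoseSpec,
    RuleEntry,
    RuleSet,
    StrategyResult,
)

_PACKAGED = {
    "objectives_clinical": "objectives_clinical.yaml",
    "objectives_phantom": "objectives_phantom.yaml",
    "rules_phantom": "rules_phantom.yaml",
    "phantom_default": "phantom_default.yaml",
}


class ConfigError(ValueError):
    """A configuration file failed schema validation."""


def packaged_path(name: str):
    """Filesystem path of a packaged default config (context-manager free
    because the package is installed from source)."""
    try:
        fname = _PACKAGED[name]
    except KeyError:
        raise KeyError(f"unknown packaged config {name!r}; have {sorted(_PACKAGED)}") from None
    return resources.files("autoplan.data").joinpath(fname)


def _read_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not data:
        raise ConfigError(f"{path}: file is empty")
    return data


# ---------------------------------------------------------------------------
# objectives


def load_objectives(path) -> list[EvaluationObjective]:
    """Parse and validate an evaluation-objectives YAML file."""
    data = _read_yaml(path)
    entries = data.get("objectives")
    if not entries:
        raise ConfigError(f"{path}: missing or empty 'objectives' list")
    out = []
    seen = set()
    for i, e in enumerate(entries):
        if not isinstance(e, dict):
            raise ConfigError(f"{path}: objectives[{i}] is not a mapping")
        try:
            obj = EvaluationObjective(
                id=str(e["id"]),
                structure=str(e["structure"]),
                level=int(e["level"]),
                metric=str(e["metric"]),
                threshold=float(e["threshold"]),
                direction=str(e["direction"]),
                metric_param=(float(e["metric_param"]) if "metric_param" in e else None),
                target_value=(float(e["target"]) if e.get("target") is not None else None),
                met_is_final=bool(e.get("met_is_final", False)),
            )
        except KeyError as exc:
            raise ConfigError(f"{path}: objectives[{i}] missing field {exc}") from None
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"{path}: objectives[{i}]: {exc}") from None
        if obj.id in seen:
            raise ConfigError(f"{path}: duplicate objective id {obj.id!r}")
        seen.add(obj.id)
        out.append(obj)
    return out


# ---------------------------------------------------------------------------
# rules


def _dose_spec(raw, path, ctx) -> DoseSpec:
    if raw is None:
        raise ConfigError(f"{path}: {ctx}: missing dose specification")
    if isinstance(raw, (int, float)):
        return DoseSpec(value=float(raw))
    if "value" in raw:
        return DoseSpec(value=float(raw["value"]))
    if "fraction" in raw:
        of = raw.get("of")
        if of not in ("rx1", "rx2", "rx3"):
            raise ConfigError(f"{path}: {ctx}: 'of' must be rx1|rx2|rx3, got {of!r}")
        return DoseSpec(fraction=float(raw["fraction"]), of=of)
    raise ConfigError(f"{path}: {ctx}: dose needs 'value' or 'fraction'/'of'")


def load_rules(path, objectives: list[EvaluationObjective] | None = None) -> RuleSet:
    """Parse and validate a planner rules YAML file.

    When ``objectives`` is supplied, additionally checks that every
    objective id has an adjustment rule.
    """
    data = _read_yaml(path)
    templates = []
    for i, e in enumerate(data.get("constraints") or []):
        ctx = f"constraints[{i}]"
        try:
            templates.append(
                ConstraintTemplate(
                    id=str(e["id"]),
                    structure=str(e["structure"]),
                    ctype=str(e["ctype"]),
                    stage=int(e["stage"]),
                    dose=_dose_spec(e.get("dose"), path, ctx),
                    volume_pct=(float(e["volume_pct"]) if "volume_pct" in e else None),
                    eud_a=float(e.get("eud_a", 1.0)),
                    dose_adjustable=bool(e.get("adjust_dose", False)),
                    step_direction=e.get("step"),
                    dose_floor=(
                        _dose_spec(e["floor"], path, ctx) if "floor" in e else DoseSpec(value=1.0)
                    ),
                    dose_ceiling=(
                        _dose_spec(e["ceiling"], path, ctx) if "ceiling" in e else None
                    ),
                )
            )
        except KeyError as exc:
            raise ConfigError(f"{path}: {ctx} missing field {exc}") from None
    if not templates:
        raise ConfigError(f"{path}: no constraint templates defined")
    rules_raw = data.get("rules") or {}
    if not rules_raw:
        raise ConfigError(f"{path}: no objective rules defined")
    rules = {}
    for oid, e in rules_raw.items():
        cids = e.get("constraints") or []
        if not cids:
            raise ConfigError(f"{path}: rule {oid!r} lists no constraints")
        rules[oid] = RuleEntry(
            constraint_ids=[str(c) for c in cids],
            actions=tuple(e.get("actions", ("raise_weight", "step_dose_up", "step_dose_down"))),
        )
    try:
        rs = RuleSet(
            templates=templates,
            rules=rules,
            ladder=tuple(int(v) for v in data.get("ladder", (1, 10, 25, 50, 75, 100))),
            step_gy=float(data.get("step_gy", 1.0)),
            rind_tighten_factor=float(data.get("rind_tighten_factor", 0.98)),
            rind_floor_fraction=float(data.get("rind_floor_fraction", 0.90)),
            sparing_step_gy=float(data.get("sparing_step_gy", 1.0)),
        )
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from None
    if objectives is not None:
        try:
            rs.validate_against(objectives)
        except ValueError as exc:
            raise ConfigError(f"{path}: {exc}") from None
    return rs


def save_rules(rules: RuleSet, path) -> None:
    """Write a RuleSet back to YAML (round-trips through load_rules)."""

    def dose_out(ds: DoseSpec):
        if ds.value is not None:
            return {"value": ds.value}
        return {"fraction": ds.fraction, "of": ds.of}

    data = {
        "constraints": [
            {
                "id": t.id,
                "structure": t.structure,
                "ctype": t.ctype,
                "stage": t.stage,
                "dose": dose_out(t.dose),
                **({"volume_pct": t.volume_pct} if t.volume_pct is not None else {}),
                "eud_a": t.eud_a,
                "adjust_dose": t.dose_adjustable,
                **({"step": t.step_direction} if t.step_direction else {}),
                "floor": dose_out(t.dose_floor),
                **({"ceiling": dose_out(t.dose_ceiling)} if t.dose_ceiling else {}),
            }
            for t in rules.templates
        ],
        "rules": {
            oid: {"constraints": list(e.constraint_ids), "actions": list(e.actions)}
            for oid, e in rules.rules.items()
        },
        "ladder": list(rules.ladder),
        "step_gy": rules.step_gy,
        "rind_tighten_factor": rules.rind_tighten_factor,
        "rind_floor_fraction": rules.rind_floor_fraction,
        "sparing_step_gy": rules.sparing_step_gy,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# phantom spec


def load_phantom_spec(path) -> PhantomSpec:
    data = _read_yaml(path)
    tuple_fields = {
        "shape", "spacing_mm", "origin_mm", "body_radii_mm", "body_center_mm",
        "ctv1_center_mm", "node2_offset_mm", "node3_offset_mm",
        "serial_oar_center_mm", "parotid_offset_mm", "prescriptions_gy",
    }
    kwargs = {}
    for key, val in data.items():
        if key in tuple_fields and val is not None:
            val = tuple(val)
        kwargs[key] = val
    try:
        return PhantomSpec(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from None


def save_phantom_spec(spec: PhantomSpec, path) -> None:
    data = {
        k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(spec).items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# run artifacts


def write_dvh_csv(path, phantom: Phantom, dose: np.ndarray,
                  structures: list[str] | None = None) -> None:
    """DVH export: one row per (structure, dose bin) with columns
    structure, dose_Gy, volume_pct."""
    names = structures or [n for n in phantom.structures if n != "body"]
    top = float(np.max(dose)) * 1.05 + 1e-6
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["structure", "dose_Gy", "volume_pct"])
        for name in names:
            curve = cumulative_dvh(dose, phantom.flat_mask(name), name, max_dose=top)
            for d, v in zip(curve.dose_gy, curve.volume_pct):
                w.writerow([name, f"{d:.4f}", f"{v:.4f}"])


def write_constraint_table(path, result: StrategyResult) -> None:
    """Final constraint set in the conventional report layout:
    (constraint, dose_Gy, weighting) rows grouped by priority stage."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["constraint", "stage", "ctype", "dose_Gy", "weighting"])
        for c in sorted(result.constraints, key=lambda c: (c.stage, c.id)):
            w.writerow([c.id, c.stage, c.ctype, f"{c.dose_gy:.2f}", c.weight])


def write_plan_json(path, result: StrategyResult) -> None:
    plan = result.final_plan
    payload = {
        "strategy": result.strategy,
        "technique": result.technique,
        "feasible": result.feasible,
        "stop_reason": result.stop_reason,
        "objective_value": None if plan is None else plan.objective_value,
        "weights": None if plan is None else plan.weights.tolist(),
        "spared_min_mean": result.spared_min_mean,
        "limiting_prescription": result.limiting_prescription,
        "limiting_objective": result.limiting_objective,
        "report": None
        if result.final_report is None
        else [
            {"id": r.id, "level": r.level, "achieved": r.achieved,
             "threshold": r.objective.threshold, "passed": r.passed}
            for r in result.final_report.results
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def write_summary(path, result: StrategyResult) -> None:
    lines = [
        f"strategy: {result.strategy}",
        f"technique: {result.technique}",
        f"feasible: {result.feasible}",
        f"stop_reason: {result.stop_reason}",
        f"iterations: {len(result.history)}",
    ]
    if result.spared_min_mean is not None:
        lines.append(f"spared_min_mean_gy: {result.spared_min_mean:.2f}")
    if result.limiting_prescription is not None:
        lines.append(f"limiting_prescription_gy: {result.limiting_prescription:.1f}")
        lines.append(f"limiting_objective: {result.limiting_objective}")
    if result.final_report is not None:
        for r in result.final_report.results:
            lines.append(
                f"  L{r.level} {r.id}: achieved {r.achieved:.2f} "
                f"(threshold {r.objective.threshold:.2f}) "
                f"{'PASS' if r.passed else 'FAIL'}"
            )
    Path(path).write_text("\n".join(lines) + "\n")
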