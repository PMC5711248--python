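"""DVH metrics and clinical evaluation objectives.

The clinical goals of a plan are expressed as *evaluation objectives*: one
pass/fail criterion per structure metric, grouped into three priority
levels (1: target coverage and global maximum, 2: serial organ limits,
3: parallel organ dose reduction).  These are distinct from the
*optimization constraints* that drive the fluence optimizer (see
:mod:`autoplan.optimize`): objectives say what a clinically acceptable plan
looks like, constraints are the knobs the automated planner turns until the
objectives are met.

Conventions
-----------
* Dv (``D_at_volume``): minimum dose to the hottest v% of a structure,
  computed as the descending-sorted voxel dose at rank ``ceil(v/100 * N)``
  with no interpolation.
* Vd (``V_at_dose``): percent of structure voxels with dose >= d.
* gEUD: power mean ``(mean(d^a))^(1/a)``; ``a = 1`` is the mean dose.
* Heterogeneity index: D5/D95, which is >= 1 for any distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .phantom import Phantom

METRICS = ("D_at_volume", "V_at_dose", "mean", "max")
DIRECTIONS = ("at_least", "at_most")


@dataclass
class EvaluationObjective:
    """One clinical pass/fail criterion.

    ``metric_param`` carries the volume level (%) for ``D_at_volume`` or the
    dose level (Gy) for ``V_at_dose``; it is unused for ``mean``/``max``.
    ``target_value`` is an optional stricter aspiration dose consulted only
    by the OAR-sparing strategy: once an OAR with a target reaches it, that
    OAR is considered settled and is no longer pushed lower.
    """

    id: str
    structure: str
    level: int
    metric: str
    threshold: float
    direction: str
    metric_param: float | None = None
    target_value: float | None = None
    met_is_final: bool = False

    def __post_init__(self):
        if self.level not in (1, 2, 3):
            raise ValueError(f"objective {self.id!r}: level must be 1, 2 or 3")
        if self.metric not in METRICS:
            raise ValueError(f"objective {self.id!r}: unknown metric {self.metric!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"objective {self.id!r}: unknown direction {self.direction!r}")
        if self.threshold <= 0:
            raise ValueError(f"objective {self.id!r}: threshold must be > 0")
        if self.metric in ("D_at_volume", "V_at_dose") and self.metric_param is None:
            raise ValueError(f"objective {self.id!r}: metric {self.metric} needs metric_param")
        if self.target_value is not None:
            stricter = (
                self.target_value < self.threshold
                if self.direction == "at_most"
                else self.target_value > self.threshold
            )
            if not stricter:
                raise ValueError(
                    f"objective {self.id!r}: target_value must be stricter than threshold"
                )


@dataclass
class DVHCurve:
    """Cumulative DVH: dose grid (Gy) vs relative volume (%) for a structure."""

    structure: str
    dose_gy: np.ndarray
    volume_pct: np.ndarray


@dataclass
class ObjectiveResult:
    objective: EvaluationObjective
    achieved: float
    passed: bool
    margin: float  # achieved - threshold, signed so that positive = pass

    @property
    def id(self) -> str:
        return self.objective.id

    @property
    def level(self) -> int:
        return self.objective.level


@dataclass
class ObjectiveReport:
    """Per-objective outcomes plus roll-up pass flags by priority level."""

    results: list[ObjectiveResult] = field(default_factory=list)

    @property
    def level_pass(self) -> dict[int, bool]:
        out = {1: True, 2: True, 3: True}
        for r in self.results:
            out[r.level] = out[r.level] and r.passed
        return out

    def all_pass(self, max_level: int = 3) -> bool:
        return all(r.passed for r in self.results if r.level <= max_level)

    def failures(self, max_level: int = 3) -> list[ObjectiveResult]:
        return [r for r in self.results if r.level <= max_level and not r.passed]

    def achieved(self, objective_id: str) -> float:
        for r in self.results:
            if r.id == objective_id:
                return r.achieved
        raise KeyError(objective_id)


# ---------------------------------------------------------------------------
# metric primitives


def _masked(dose: np.ndarray, mask: np.ndarray) -> np.ndarray:
    dose = np.asarray(dose, dtype=float).ravel()
    mask = np.asarray(mask, dtype=bool).ravel()
    if dose.shape != mask.shape:
        raise ValueError("dose vector and mask have different lengths")
    vals = dose[mask]
    if vals.size == 0:
        raise ValueError("empty structure mask")
    return vals


def cumulative_dvh(dose: np.ndarray, mask: np.ndarray, structure: str = "",
                   n_bins: int = 512, max_dose: float | None = None) -> DVHCurve:
    """Cumulative dose-volume histogram for one structure.

    The curve value at dose d is ``100 * #(voxels with dose >= d) / N``.
    """
    vals = _masked(dose, mask)
    top = max_dose if max_dose is not None else max(float(vals.max()) * 1.05, 1e-6)
    grid = np.linspace(0.0, top, n_bins)
    vol = 100.0 * (vals[None, :] >= grid[:, None]).mean(axis=1)
    return DVHCurve(structure, grid, vol)


def dose_at_volume(dose: np.ndarray, mask: np.ndarray, v_percent: float) -> float:
    """Dv: descending-sorted voxel dose at rank ceil(v/100 * N), no interpolation."""
    if not 0 < v_percent <= 100:
        raise ValueError("volume percentage must be in (0, 100]")
    vals = np.sort(_masked(dose, mask))[::-1]
    rank = math.ceil(v_percent / 100.0 * vals.size)
    return float(vals[rank - 1])


def volume_at_dose(dose: np.ndarray, mask: np.ndarray, d_gray: float) -> float:
    """Vd: percent of structure voxels receiving at least d Gy."""
    if d_gray < 0:
        raise ValueError("dose level must be >= 0")
    vals = _masked(dose, mask)
    return 100.0 * float((vals >= d_gray).mean())


def eud(dose: np.ndarray, mask: np.ndarray, a: float) -> float:
    """Generalized equivalent uniform dose: the power-a mean of voxel doses."""
    if a == 0:
        raise ValueError("gEUD exponent a must be nonzero (geometric mean unsupported)")
    vals = _masked(dose, mask)
    if a == 1:
        return float(vals.mean())
    if np.any(vals < 0):
        raise ValueError("negative dose in gEUD")
    return float(np.mean(vals**a) ** (1.0 / a))


def heterogeneity_index(dose: np.ndarray, mask: np.ndarray) -> float:
    """Target dose heterogeneity D5/D95 (>= 1 for any distribution)."""
    d5 = dose_at_volume(dose, mask, 5.0)
    d95 = dose_at_volume(dose, mask, 95.0)
    if d95 == 0:
        raise ValueError("heterogeneity index undefined: D95 is zero")
    return d5 / d95


# ---------------------------------------------------------------------------
# objective evaluation


def _achieved_value(dose: np.ndarray, phantom: Phantom, obj: EvaluationObjective) -> float:
    mask = phantom.flat_mask(obj.structure)
    if obj.metric == "D_at_volume":
        return dose_at_volume(dose, mask, obj.metric_param)
    if obj.metric == "V_at_dose":
        return volume_at_dose(dose, mask, obj.metric_param)
    if obj.metric == "mean":
        return float(_masked(dose, mask).mean())
    if obj.metric == "max":
        return float(_masked(dose, mask).max())
    raise ValueError(f"objective {obj.id!r}: unknown metric {obj.metric!r}")


def evaluate_objectives(
    dose: np.ndarray, phantom: Phantom, objectives: list[EvaluationObjective]
) -> ObjectiveReport:
    """Evaluate every objective against a dose distribution.

    Pure function of its inputs; results are ordered by (level, input order).
    Raises if an objective names a structure the phantom does not have.
    """
    for obj in objectives:
        if obj.structure not in phantom:
            raise KeyError(
                f"objective {obj.id!r} references unknown structure {obj.structure!r}"
            )
    results = []
    order = sorted(range(len(objectives)), key=lambda i: (objectives[i].level, i))
    for i in order:
        obj = objectives[i]
        achieved = _achieved_value(dose, phantom, obj)
        if obj.direction == "at_least":
            passed = achieved >= obj.threshold
            margin = achieved - obj.threshold
        else:
            passed = achieved <= obj.threshold
            margin = obj.threshold - achieved
        results.append(ObjectiveResult(obj, achieved, bool(passed), float(margin)))
    return ObjectiveReport(results)
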