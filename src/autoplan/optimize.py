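"""Weighted multi-constraint fluence-map optimization.

Stands in for the proprietary optimizer of a commercial treatment planning
system: minimize, over non-negative beamlet weights w, a weighted sum of
one-sided quadratic and gEUD penalties on the dose d = A w,

    F(w) = sum_c  weight_c * cost_c(A w),

with per-structure costs normalized by voxel count so that structure size
does not swamp the penalty weights.  Constraint forms:

* ``max_dose``:   mean over the mask of (d - D)_+^2
* ``min_dose``:   mean of (D - d)_+^2
* ``uniform_dose``: mean of (d - D)^2
* ``min_dvh`` / ``max_dvh``: the one-sided quadratic applied only to the
  violating voxel subset selected by the current DVH rank (Bortfeld-style);
  the subset is recomputed at each outer solver iteration, not during line
  search, for stability.
* ``max_eud``:    (gEUD_a - D)_+^2 (unnormalized: gEUD already averages).

The solver is a projected gradient method with backtracking line search
under w >= 0, warm-startable from a previous plan's weights.  It is
deterministic: identical inputs and options give identical output.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .dose import InfluenceMatrix
from .metrics import dose_at_volume, eud
from .phantom import Phantom

#: the permitted penalty-weight ladder
WEIGHT_LADDER = (1, 10, 25, 50, 75, 100)

CTYPES = ("min_dose", "max_dose", "min_dvh", "max_dvh", "uniform_dose", "max_eud")


@dataclass
class OptimizationConstraint:
    """One penalty term of the fluence objective.

    ``step_direction`` records which way the automated planner may move
    ``dose_gy`` when the weight ladder is exhausted ('up' for coverage,
    'down' for sparing constraints, None for fixed doses).  ``dose_floor`` /
    ``dose_ceiling`` bound those steps; a ceiling of None defers to the
    same-structure conflict rule applied by the planner.
    """

    id: str
    structure: str
    ctype: str
    dose_gy: float
    weight: int = 1
    volume_pct: float | None = None
    eud_a: float = 1.0
    stage: int = 1  # priority stage at which the constraint enters
    weight_adjustable: bool = True
    dose_adjustable: bool = False
    step_direction: str | None = None
    dose_floor: float = 1.0
    dose_ceiling: float | None = None

    def __post_init__(self):
        if self.ctype not in CTYPES:
            raise ValueError(f"constraint {self.id!r}: unknown ctype {self.ctype!r}")
        if self.dose_gy <= 0:
            raise ValueError(f"constraint {self.id!r}: dose_gy must be > 0")
        if self.weight not in WEIGHT_LADDER:
            raise ValueError(
                f"constraint {self.id!r}: weight {self.weight} not in ladder {WEIGHT_LADDER}"
            )
        if self.ctype in ("min_dvh", "max_dvh") and self.volume_pct is None:
            raise ValueError(f"constraint {self.id!r}: DVH constraint needs volume_pct")


def constraint_state_hash(constraints: list[OptimizationConstraint]) -> str:
    """Stable short hash of (id, dose, weight) triples, for history records."""
    h = hashlib.sha256()
    for c in sorted(constraints, key=lambda c: c.id):
        h.update(f"{c.id}:{c.dose_gy:.6f}:{c.weight};".encode())
    return h.hexdigest()[:12]


@dataclass
class SolverOptions:
    """Projected-gradient solver settings."""

    max_iterations: int = 200
    tol: float = 1e-6
    initial_weight: float | None = None  # None -> auto-scaled uniform start
    normalize_by_voxels: bool = True
    max_outer_rounds: int = 8

    def __post_init__(self):
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class Plan:
    """Optimizer output: weights, dose, and convergence bookkeeping."""

    weights: np.ndarray
    dose: np.ndarray
    technique: str
    objective_value: float
    converged: bool
    #: the weights the solve started from (enables exact replay)
    start_weights: np.ndarray | None = None
    obj_trace: list[float] = field(default_factory=list)
    round_starts: list[int] = field(default_factory=list)
    constraint_hash: str = ""


# ---------------------------------------------------------------------------
# penalty terms


def dvh_violating_subset(
    dose: np.ndarray, phantom: Phantom, c: OptimizationConstraint
) -> np.ndarray:
    """Flat boolean mask of the voxels a DVH constraint currently penalizes.

    For a min-DVH constraint (at least V% of the structure >= D) the subset
    is the warmest deficient voxels: dose in [Dv, D).  For a max-DVH
    constraint it is the coolest offending voxels: dose in (D, D_V].  Voxels
    outside the subset receive zero gradient from the constraint.
    """
    mask = phantom.flat_mask(c.structure)
    dose = np.asarray(dose, dtype=float).ravel()
    dv = dose_at_volume(dose, mask, c.volume_pct)
    sub = np.zeros_like(mask)
    if c.ctype == "min_dvh":
        if dv < c.dose_gy:
            sub = mask & (dose >= dv) & (dose < c.dose_gy)
    elif c.ctype == "max_dvh":
        if dv > c.dose_gy:
            sub = mask & (dose > c.dose_gy) & (dose <= dv)
    else:
        raise ValueError(f"constraint {c.id!r} is not a DVH constraint")
    return sub


def constraint_cost(
    dose: np.ndarray,
    phantom: Phantom,
    c: OptimizationConstraint,
    dvh_subset: np.ndarray | None = None,
    normalize: bool = True,
) -> tuple[float, np.ndarray]:
    """Cost and exact analytic dose-gradient of one constraint.

    Cost is >= 0 and equals 0 iff the constraint is satisfied on every
    relevant voxel.  For DVH constraints the penalized subset may be frozen
    by passing ``dvh_subset`` (the solver does this within a line search).
    """
    dose = np.asarray(dose, dtype=float).ravel()
    mask = phantom.flat_mask(c.structure)
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"constraint {c.id!r}: structure {c.structure!r} is empty")
    norm = float(n) if normalize else 1.0
    grad = np.zeros_like(dose)
    d = c.dose_gy

    if c.ctype == "max_dose":
        exc = np.maximum(dose[mask] - d, 0.0)
        cost = float(np.dot(exc, exc)) / norm
        grad[mask] = 2.0 * exc / norm
    elif c.ctype == "min_dose":
        deficit = np.maximum(d - dose[mask], 0.0)
        cost = float(np.dot(deficit, deficit)) / norm
        grad[mask] = -2.0 * deficit / norm
    elif c.ctype == "uniform_dose":
        diff = dose[mask] - d
        cost = float(np.dot(diff, diff)) / norm
        grad[mask] = 2.0 * diff / norm
    elif c.ctype in ("min_dvh", "max_dvh"):
        sub = dvh_subset if dvh_subset is not None else dvh_violating_subset(dose, phantom, c)
        diff = dose[sub] - d
        cost = float(np.dot(diff, diff)) / norm
        grad[sub] = 2.0 * diff / norm
    elif c.ctype == "max_eud":
        e = eud(dose, mask, c.eud_a)
        over = max(e - d, 0.0)
        cost = over * over
        if over > 0:
            vals = dose[mask]
            if c.eud_a == 1:
                de = np.full(n, 1.0 / n)
            else:
                # dE/dd_i = (1/n) d_i^(a-1) E^(1-a); clamp to avoid 0^negative
                safe = np.maximum(vals, 1e-9)
                de = (safe ** (c.eud_a - 1.0)) * (max(e, 1e-9) ** (1.0 - c.eud_a)) / n
            grad[mask] = 2.0 * over * de
    else:  # pragma: no cover - guarded by the dataclass validator
        raise ValueError(f"unknown constraint type {c.ctype!r}")
    return cost, grad


def total_objective(
    dose: np.ndarray,
    phantom: Phantom,
    constraints: list[OptimizationConstraint],
    dvh_subsets: dict[str, np.ndarray] | None = None,
    normalize: bool = True,
) -> tuple[float, np.ndarray]:
    """Weighted sum of constraint costs with additive gradient."""
    if not constraints:
        raise ValueError("constraint list is empty")
    total = 0.0
    grad = np.zeros(np.asarray(dose).size)
    for c in constraints:
        sub = dvh_subsets.get(c.id) if dvh_subsets else None
        cost, g = constraint_cost(dose, phantom, c, dvh_subset=sub, normalize=normalize)
        total += c.weight * cost
        grad += c.weight * g
    return total, grad


# ---------------------------------------------------------------------------
# projected-gradient solver


def _initial_weights(matrix: InfluenceMatrix, phantom: Phantom,
                     opts: SolverOptions) -> np.ndarray:
    if opts.initial_weight is not None:
        return np.full(matrix.n_beamlets, float(opts.initial_weight))
    # scale a uniform fluence so the primary target mean matches prescription
    w = np.ones(matrix.n_beamlets)
    d = matrix.matrix @ w
    if "ptv1" in phantom:
        ref = float(d[phantom.flat_mask("ptv1")].mean())
        target = phantom.prescriptions_gy[0]
    else:
        ref = float(d.max())
        target = 1.0
    if ref > 0:
        w *= target / ref
    return w


def solve_weights(
    matrix: InfluenceMatrix,
    phantom: Phantom,
    constraints: list[OptimizationConstraint],
    opts: SolverOptions = SolverOptions(),
    warm_start: np.ndarray | None = None,
) -> Plan:
    """Minimize the weighted penalty sum over non-negative beamlet weights.

    Projected gradient with backtracking line search.  DVH violating subsets
    are refreshed between outer rounds; within a round the smooth
    fixed-subset objective decreases monotonically.  The returned weights
    never score a higher true objective than the starting point (the start
    is returned unchanged if no improving step exists, e.g. when every
    constraint is already satisfied and the gradient vanishes).
    """
    A = matrix.matrix
    w0 = (
        np.maximum(np.asarray(warm_start, dtype=float).copy(), 0.0)
        if warm_start is not None
        else _initial_weights(matrix, phantom, opts)
    )
    if w0.shape[0] != matrix.n_beamlets:
        raise ValueError("warm-start weight vector has wrong length")
    norm = opts.normalize_by_voxels

    def true_obj(w):
        f, _ = total_objective(A @ w, phantom, constraints, normalize=norm)
        return f

    def subsets_for(dose):
        return {
            c.id: dvh_violating_subset(dose, phantom, c)
            for c in constraints
            if c.ctype in ("min_dvh", "max_dvh")
        }

    w = w0.copy()
    dose = A @ w
    trace: list[float] = []
    round_starts: list[int] = []
    iters_left = opts.max_iterations
    converged = False
    f_round_prev = None

    for _ in range(opts.max_outer_rounds):
        if iters_left <= 0:
            break
        subs = subsets_for(dose)
        f, g_d = total_objective(dose, phantom, constraints, subs, normalize=norm)
        if not np.isfinite(f):
            raise FloatingPointError("non-finite optimization objective")
        round_starts.append(len(trace))
        trace.append(f)
        if f_round_prev is not None and abs(f_round_prev - f) <= opts.tol * max(f_round_prev, 1.0):
            converged = True
            break
        f_round_prev = f
        g_w = A.T @ g_d
        t = None
        stalled = False
        while iters_left > 0:
            iters_left -= 1
            gnorm2 = float(np.dot(g_w, g_w))
            if gnorm2 <= 1e-30:
                converged = True
                stalled = True
                break
            if t is None:
                t = f / gnorm2 if f > 0 else 1.0
            accepted = False
            for _bt in range(40):
                w_new = np.maximum(w - t * g_w, 0.0)
                step = w_new - w
                if not np.any(step):
                    break
                dose_new = A @ w_new
                f_new, _ = total_objective(dose_new, phantom, constraints, subs, normalize=norm)
                if f_new <= f - 1e-4 / max(t, 1e-30) * float(np.dot(step, step)):
                    accepted = True
                    break
                t *= 0.5
            if not accepted:
                stalled = True
                break
            rel_drop = (f - f_new) / max(f, 1e-30)
            w, dose, f = w_new, dose_new, f_new
            trace.append(f)
            _, g_d = total_objective(dose, phantom, constraints, subs, normalize=norm)
            g_w = A.T @ g_d
            t *= 2.0  # optimistic growth; backtracking trims it again
            if rel_drop <= opts.tol:
                break
        if stalled and converged:
            break
        if stalled:
            # no improving step under the current subsets
            converged = True
            break

    # safeguard the descent contract under the true (refreshed-subset) objective
    f_final = true_obj(w)
    f_start = true_obj(w0)
    if f_final > f_start:
        w, dose, f_final = w0, A @ w0, f_start
        converged = False
    return Plan(
        weights=w,
        dose=A @ w,
        technique=matrix.basis.technique,
        objective_value=f_final,
        converged=converged,
        start_weights=w0,
        obj_trace=trace,
        round_starts=round_starts,
        constraint_hash=constraint_state_hash(constraints),
    )
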