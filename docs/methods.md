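# Methods

## What this package models

The package re-implements, end to end on synthetic data, a *bias-free
automated inverse-planning* procedure for comparing two radiotherapy
delivery techniques — fixed seven-field IMRT and rotational (arc) delivery
— without a human planner in the loop.  The scientific object of interest
is the planning *procedure*, not a dose engine: a rule-driven loop that
repeatedly (i) solves a fluence optimization for the current constraint
set, (ii) evaluates a fixed, three-level list of clinical pass/fail
objectives, and (iii) either repairs the highest-priority failing
objective using predefined adjustment rules, or — when everything passes —
makes strategy-specific progress (tightening conformity shells, lowering a
spared organ's constraint, or escalating the prescription).  Because the
objectives, the rules and the stopping criteria are fixed a priori and
identical for both techniques, any difference in the outcome is
attributable to the technique, not the operator.

Three strategies are implemented:

* **standard** — reach a plan meeting every objective, then tighten the
  rind (dummy shell) constraints while all objectives continue to pass;
* **spare** — from a standard plan, lower the spared organ's mean-dose
  (gEUD, a=1) constraint in 1 Gy steps until a higher-level objective
  irreversibly fails, then roll back; the reported quantity is the lowest
  accepted mean dose;
* **escalate** — isotoxic escalation: raise the primary-target
  prescription in 2 Gy steps, rescaling every prescription-linked
  threshold and constraint, until no permitted adjustment can restore an
  all-pass state; the reported quantity is the last all-pass prescription
  and the objective that blocked the next step.

## The adjustment rules

Constraints enter in three priority stages (targets + global maximum;
serial organs at risk; parallel OARs + rind shells), all with penalty
weight 1.  For a failing objective the associated constraint first climbs
the weight ladder 1 → 10 → 25 → 50 → 75 → 100; only at weight 100 may its
dose step, 1 Gy at a time — upward for coverage constraints, downward for
sparing constraints.  A coverage constraint may not step past the same
structure's uniform/maximum-dose constraint (the conflict rule that is
also the usual stopping condition of the standard strategy), and sparing
constraints stop at a configured floor.  One action is taken per
iteration, always for the highest-priority failure; every all-pass state
is snapshotted, and when no action remains the planner rolls back to the
last snapshot — a plan counts only if it meets every objective.  Rind
tightening multiplies the shell constraint doses by 0.98 per all-pass
iteration, floored at 90% of the corresponding PTV prescription (the
tightening magnitude is a design choice; only "tightening while feasible"
is prescribed by the procedure being modelled).

The rules live in a machine-readable YAML "initialization file"
(`data/rules_phantom.yaml`): constraint templates with prescription-linked
doses, the objective-to-constraint mapping, permitted action kinds, the
ladder and the step sizes.  Every evaluation objective must map to at
least one constraint; the loader enforces this.

## Evaluation objectives

Objectives mirror a three-dose-level head-and-neck SIB protocol
(70/63/56 Gy in 33 fractions): level 1 — PTV coverage (D95 ≥ 95% and
D99 ≥ 90% of each prescription) and a whole-body maximum at 110% of the
primary prescription; level 2 — serial-organ PRV maxima; level 3 —
parallel-organ mean doses (parotid surrogate: mean ≤ 26 Gy).  Dv uses the
descending-sorted voxel dose at rank ceil(v/100·N) with no interpolation —
deterministic and directly checkable against exhaustive counting.  The
whole-body maximum is tied to the live prescription (110%) rather than a
fixed 77 Gy so that the escalation strategy remains coherent; a fixed cap
would trivially bound escalation at ~81 Gy.  The heterogeneity index is
reported as D5/D95, which is ≥ 1 by construction.  The fraction count is
bookkeeping only; all doses are total Gy.

## Synthetic phantom and what it does (not) represent

A single axial head-and-neck-like slice on a 2.5 mm grid (88×96 voxels):
an elliptical body, a central primary CTV with two nested nodal levels
placed laterally (unilateral or bilateral), a serial-OAR surrogate
(cord/brainstem-like, 5 mm radius + 5 mm PRV margin) posterior to the
primary PTV, and paired lateral parallel-OAR surrogates (parotid-like).
CTVs expand to PTVs by a uniform 3 mm margin under a voxel-centre
Euclidean convention (anisotropic spacing honoured, exact distance
transform); 10 mm rind shells surround each PTV.  Structure masks are
used raw — overlapping structures are not trimmed, and PTVs are not
cropped at the skin (configurable).

Two placements are deliberate, because they create the trade-offs the
planning strategies exist to negotiate: the parotid surrogates overlap
the low-dose nodal PTV by several millimetres (as medial parotid lobes
overlap nodal volumes clinically), so their mean dose cannot be driven
arbitrarily low without failing coverage; and the serial-OAR PRV sits
within a few millimetres of the primary PTV, so escalation eventually
fails an objective rather than running away.  The phantom reproduces the
*topology* of the clinical problem, not patient anatomy: absolute dose
metrics, step counts and limiting prescriptions are properties of this
surrogate and are not comparable to clinical values.  Passing tests show
the procedure behaves correctly (priority discipline, rollback, monotone
traces, feasibility); they say nothing about dosimetric accuracy on real
patients.

The cohort generator jitters target radii, nodal/parotid placement and
the serial-OAR gap (±1.5–2 mm ranges) and alternates
unilateral/bilateral nodal disease, giving ten distinct, deterministic
cases per seed; jitter ranges are small enough that the standard strategy
is feasible for every default case.

## Dose engine

Each gantry angle carries a row of independent 5 mm fluence beamlets
covering the largest target's lateral projection plus one beamlet margin.
The per-beamlet kernel is primary-only: exponential depth attenuation
(mu = 0.004/mm) times a lateral Gaussian (sigma = 4 mm, truncated at
3.5 sigma), zero outside the body; depth is ray-marched from the body
surface at one-voxel steps.  Delivery constraints (apertures, MU,
segments, delivery time) are intentionally absent — the comparison is
between angular-freedom classes, with the arc basis collapsing a dual-arc
geometry onto one set of directions (4° control-point spacing gives the
standard 90 directions; cohort runs use 10° as a desk-scale choice).
The 4 mm lateral spread is wider than a clinical pencil beam on purpose:
on a 2.5 mm grid a 3 mm kernel produces penumbras so sharp that an arc
basis can carve dose around every OAR indefinitely and isotoxic
escalation never terminates; with 4 mm the OAR-proximity physics that the
procedure is designed to negotiate actually binds.  Columns that never
intersect the body are pruned.

## Fluence optimizer

Minimizes `sum_c weight_c * cost_c(A w)` over non-negative beamlet
weights: one-sided quadratics for min/max/uniform dose (normalized per
structure by voxel count so large structures do not swamp the weights),
rank-selected one-sided quadratics for DVH constraints (violating subset
recomputed between outer rounds, frozen within a line search), and a
one-sided quadratic on gEUD.  Gradients are exact.  The solver is
projected gradient with backtracking (Armijo) line search and an adaptive
initial step, warm-started between planner iterations from the previous
plan's weights to emulate "continue optimization" behaviour (cold start
is an option).  Defaults: 200 inner iterations, relative-change tolerance
1e-6; cohort runs use 60 iterations at 1e-5 — sufficient because the
planner re-solves every iteration from a warm start.  The returned
weights never score worse than the starting point (the start is returned
if no improving step exists), which gives exact replayability of any
logged iteration: re-solving a snapshot's constraint set from its stored
start weights reproduces the plan bit for bit.

The cold-start point is a uniform fluence scaled so the primary target's
mean equals its prescription; the cost forms and normalizations are
declared surrogates for a commercial optimizer's proprietary internals,
so all claims about the optimizer are property-based (descent,
non-negativity, gradient correctness), not value-based.

## Paired statistics

The Wilcoxon signed-rank test is exact: zero differences discarded,
average ranks over ties, and the two-sided p computed from the complete
2^n sign-assignment distribution (built by convolution on a half-rank
integer grid) for n ≤ 20, with a tie-corrected normal approximation above.
p = min(1, 2·min(P(W+ ≤ w), P(W+ ≥ w))).  The packaged reference cohorts
(ten patients each: minimum parotid means under sparing; limiting
prescriptions under escalation) transcribe the printed per-patient values
*and* the printed difference column separately, because printed
differences are not always the exact column difference; annotated
inconsistencies are preserved, not corrected.  Subgroup summaries use the
sample (n−1) standard deviation.

## Numerical choices and edge cases

* Margin expansion includes centres at exactly the margin distance
  (1e-9 mm slack on the exact Euclidean distance transform).
* Dv ranks avoid interpolation entirely; ties in voxel dose resolve by
  the sort order of identical values (indistinguishable in the result).
* The gEUD gradient clamps voxel doses at 1e-9 Gy to avoid 0^(a−1) for
  a < 1; exponents are configurable per constraint (a = 1 for parallel
  organs by default).
* Degenerate inputs fail loudly: empty masks, zero-volume PTVs, all-zero
  paired differences, weights off the ladder, unknown structures or
  constraint types all raise with the offending name.
* Escalation has a 130 Gy safety cap; a case whose anatomy tolerates more
  than the cap reports the cap as its (censored) limit with no limiting
  objective.  On the default phantom both techniques hit a genuine limit
  well below the cap.
* Iteration caps: 150 planner iterations per strategy; each strategy also
  terminates structurally (finite ladder, bounded dose ranges, monotone
  rind/sparing/escalation progressions).

## Known limitations

Single-slice geometry (3D is supported by the mask/margin machinery but
not the ray tracer); no build-up, scatter, or heterogeneity; no
deliverability constraints, so absolute sparing and escalation numbers
are optimistic relative to any deliverable plan; the greedy one-action
loop is path-dependent, so per-case paired differences between techniques
carry algorithmic as well as dosimetric variance — conclusions should be
drawn at cohort level, as the procedure intends.
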