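# autoplan

Bias-free automated inverse treatment planning, self-contained on
synthetic phantoms — for medical physicists and algorithm developers who
want to study *planner-free* technique comparison (fixed-field IMRT vs
rotational/arc delivery) without a commercial treatment planning system or
patient data.

## The problem and the procedure

Planning studies that compare delivery techniques are confounded by the
human planner: experience and expectation bias leak into the optimization
constraints.  The remedy implemented here is a fully automated planning
loop whose inputs — a prioritized list of clinical *evaluation objectives*
and a predefined *rule file* saying which optimization constraint to
change when an objective fails, and how — are fixed a priori and identical
for both techniques.

Each iteration solves a fluence optimization, evaluates the objectives,
and repairs the highest-priority failure by climbing a penalty-weight
ladder (1, 10, 25, 50, 75, 100) and then, at maximum weight, stepping the
constraint dose in 1 Gy increments; coverage constraints may not step past
the same structure's uniform-dose constraint (a conflict), and whenever no
permitted adjustment remains the planner **rolls back** to the last
constraint set that met every objective.  Objectives follow a three-level
priority scheme for a 70/63/56 Gy simultaneous-integrated-boost protocol
(target coverage D95/D99 and global maximum; serial-organ PRV maxima;
parallel-organ mean doses), evaluated as DVH metrics
(Dv = descending-rank voxel dose at ceil(v·N/100), gEUD = power-a mean).

Three strategies build on the loop:

| strategy | progress move when all objectives pass | reported quantity |
|---|---|---|
| `standard` | tighten rind (dummy shell) constraints | final plan + DVH metrics |
| `spare` | lower the spared OAR's mean-dose constraint 1 Gy | minimum accepted OAR mean (Gy) |
| `escalate` | raise the primary prescription 2 Gy, rescale linked limits | limiting prescription (Gy) + limiting objective |

Everything needed to exercise the procedure ships with the package: a
deterministic head-and-neck-like voxel phantom generator (nested PTVs,
cord-like serial OAR + PRV, parotid-like parallel OARs, unilateral or
bilateral nodal disease), a pencil-beam dose-influence engine
(`exp(-mu·depth)·exp(-r²/2σ²)`, dose linear in beamlet weights), a
projected-gradient fluence optimizer with exact analytic gradients, a
jittered ten-case paired cohort generator, and an exact (full 2ⁿ
enumeration) Wilcoxon signed-rank test for the paired comparison.
See `docs/methods.md` for models, assumptions and limitations.

## Worked example

Run the standard strategy on the default phantom with the seven-field
technique:

```sh
$ autoplan run --strategy standard --technique imrt7 --out demo
strategy: standard
technique: imrt7
feasible: True
stop_reason: complete
iterations: 53
  L1 ptv1_d95: achieved 67.10 (threshold 66.50) PASS
  L1 ptv1_d99: achieved 63.67 (threshold 63.00) PASS
  L1 ptv2_d95: achieved 60.14 (threshold 59.90) PASS
  L1 ptv2_d99: achieved 56.88 (threshold 56.70) PASS
  L1 ptv3_d95: achieved 53.85 (threshold 53.20) PASS
  L1 ptv3_d99: achieved 50.70 (threshold 50.40) PASS
  L1 body_max: achieved 73.56 (threshold 77.00) PASS
  L2 cord_max: achieved 49.00 (threshold 50.00) PASS
  L3 parotid_l_mean: achieved 25.01 (threshold 26.00) PASS
  L3 parotid_r_mean: achieved 25.02 (threshold 26.00) PASS
```

The loop needed 53 iterations to satisfy all ten objectives and then
exhaust the rind tightening; every coverage objective sits just above its
threshold and every organ limit just below — the planner drives doses
toward their tolerances, as the rules intend.  `demo/` contains the plan
(weights + metadata JSON), per-structure DVH curves (CSV), the iteration
log (JSONL, one record per solve/evaluate/adjust cycle) and the final
constraint table.

The paired analysis of the packaged ten-patient reference cohort
(minimum mean parotid doses under the sparing strategy, IMRT vs VMAT):

```sh
$ autoplan compare --fixture sparing
n = 10
mean A (IMRT): 19.6   mean B (VMAT): 17.0
mean difference A-B: 2.55 (printed column: 2.52)
max |difference|: 6.0
Wilcoxon signed-rank: W = 0.0, exact two-sided p = 0.00195312 (n = 10)
```

All ten differences favour the rotational technique, so the exact
two-sided p-value is the extreme-tail mass 2/2¹⁰ = 0.00195: the sparing
advantage is significant at p < 0.01.

A full synthetic paired study (10 jittered cases × both techniques):

```sh
autoplan cohort --strategy spare --cases 10 --seed 1
```

Library use mirrors the CLI: `build_phantom`, `beam_geometry` /
`influence_matrix`, `planning_loop` / `oar_sparing_loop` /
`dose_escalation_loop`, `default_cohort` / `run_cohort`, and
`wilcoxon_exact` are all importable from `autoplan`.

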