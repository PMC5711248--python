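"""Penalty costs, analytic gradients and the projected-gradient solver."""

import numpy as np
import pytest

from autoplan.optimize import (
    OptimizationConstraint,
    SolverOptions,
    constraint_cost,
    dvh_violating_subset,
    solve_weights,
    total_objective,
)

from conftest import make_toy_matrix, make_toy_phantom


def toy(masks, n, roles=None):
    return make_toy_phantom(
        {k: np.array(v, bool) for k, v in masks.items()}, (n,), roles=roles or {}
    )


class TestConstraintCost:
    def test_satisfied_max_dose_zero(self):
        ph = toy({"oar": [1, 1, 1, 0]}, 4, roles={"oar": "serial_oar"})
        c = OptimizationConstraint("c", "oar", "max_dose", 50.0)
        cost, grad = constraint_cost(np.array([10.0, 20.0, 30.0, 99.0]), ph, c)
        assert cost == 0.0 and not grad.any()

    def test_uniform_at_prescription_zero(self):
        ph = toy({"ptv1": [1, 1, 1, 1]}, 4)
        c = OptimizationConstraint("c", "ptv1", "uniform_dose", 70.0)
        cost, _ = constraint_cost(np.full(4, 70.0), ph, c)
        assert cost == 0.0

    def test_max_dose_hand_value(self):
        """Two-voxel mask, doses {72, 68}, limit 70: mean one-sided square = 2."""
        ph = toy({"oar": [1, 1]}, 2, roles={"oar": "serial_oar"})
        c = OptimizationConstraint("c", "oar", "max_dose", 70.0)
        cost, grad = constraint_cost(np.array([72.0, 68.0]), ph, c)
        assert cost == pytest.approx(2.0)
        assert grad[0] == pytest.approx(2.0 * 2.0 / 2) and grad[1] == 0.0

    def test_min_dose_hand_value(self):
        ph = toy({"ptv1": [1, 1]}, 2)
        c = OptimizationConstraint("c", "ptv1", "min_dose", 70.0)
        cost, grad = constraint_cost(np.array([65.0, 71.0]), ph, c)
        assert cost == pytest.approx(25.0 / 2)
        assert grad[0] < 0 and grad[1] == 0.0

    def test_eud_hand_value(self):
        ph = toy({"oar": [1, 1]}, 2, roles={"oar": "parallel_oar"})
        c = OptimizationConstraint("c", "oar", "max_eud", 5.0, eud_a=2.0)
        cost, _ = constraint_cost(np.array([0.0, 10.0]), ph, c)
        assert cost == pytest.approx((np.sqrt(50.0) - 5.0) ** 2)

    def test_dvh_penalty_selectivity(self):
        """Voxels outside the rank-selected violating subset get no gradient."""
        ph = toy({"ptv1": [1] * 10}, 10)
        dose = np.arange(1.0, 11.0)  # D95 = 1 < 8: violated
        c = OptimizationConstraint("c", "ptv1", "min_dvh", 8.0, volume_pct=95.0)
        sub = dvh_violating_subset(dose, ph, c)
        cost, grad = constraint_cost(dose, ph, c)
        assert cost > 0
        assert (grad[~sub] == 0).all() and (grad[sub] != 0).all()
        # satisfied case: empty subset, zero cost
        c_ok = OptimizationConstraint("c2", "ptv1", "min_dvh", 1.0, volume_pct=95.0)
        assert not dvh_violating_subset(dose, ph, c_ok).any()
        assert constraint_cost(dose, ph, c_ok)[0] == 0.0

    def test_unknown_ctype_rejected(self):
        with pytest.raises(ValueError, match="ctype"):
            OptimizationConstraint("c", "s", "soft_max", 10.0)

    def test_weight_outside_ladder_rejected(self):
        with pytest.raises(ValueError, match="ladder"):
            OptimizationConstraint("c", "s", "max_dose", 10.0, weight=42)


class TestTotalObjective:
    def _setup(self):
        rng = np.random.default_rng(5)
        ph = toy(
            {
                "ptv1": [1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0],
                "oar": [0, 0, 0, 0, 0, 1, 1, 1, 0, 0, 0, 0],
            },
            12,
            roles={"oar": "serial_oar"},
        )
        dose = rng.random(12) * 80
        constraints = [
            OptimizationConstraint("a", "ptv1", "min_dose", 63.0),
            OptimizationConstraint("b", "ptv1", "uniform_dose", 70.0),
            OptimizationConstraint("c", "oar", "max_dose", 30.0, weight=10),
            OptimizationConstraint("d", "oar", "max_eud", 10.0, eud_a=2.0, weight=25),
            OptimizationConstraint("e", "ptv1", "min_dvh", 66.5, volume_pct=80.0),
        ]
        return ph, dose, constraints

    def test_single_constraint_weight_one(self):
        ph, dose, cs = self._setup()
        f, g = total_objective(dose, ph, [cs[0]])
        f0, g0 = constraint_cost(dose, ph, cs[0])
        assert f == f0 and np.array_equal(g, g0)

    def test_linear_in_weight(self):
        ph, dose, cs = self._setup()
        import dataclasses

        c1 = dataclasses.replace(cs[0], weight=1)
        c10 = dataclasses.replace(cs[0], weight=10)
        assert total_objective(dose, ph, [c10])[0] == pytest.approx(
            10 * total_objective(dose, ph, [c1])[0]
        )

    def test_gradient_matches_central_finite_differences(self):
        ph, dose, cs = self._setup()
        subsets = {
            c.id: dvh_violating_subset(dose, ph, c)
            for c in cs
            if c.ctype in ("min_dvh", "max_dvh")
        }
        f, grad = total_objective(dose, ph, cs, dvh_subsets=subsets)
        h = 1e-5
        for i in range(len(dose)):
            dp, dm = dose.copy(), dose.copy()
            dp[i] += h
            dm[i] -= h
            fp = total_objective(dp, ph, cs, dvh_subsets=subsets)[0]
            fm = total_objective(dm, ph, cs, dvh_subsets=subsets)[0]
            fd = (fp - fm) / (2 * h)
            assert grad[i] == pytest.approx(fd, rel=1e-5, abs=1e-7)

    def test_empty_constraints_rejected(self):
        ph, dose, _ = self._setup()
        with pytest.raises(ValueError):
            total_objective(dose, ph, [])


class TestSolveWeights:
    def test_fixed_point_single_voxel(self):
        """1 voxel, 1 beamlet, entry 0.5, min dose 70: weight -> 140."""
        ph = toy({"ptv1": [1]}, 1)
        m = make_toy_matrix([[0.5]], (1,))
        c = OptimizationConstraint("c", "ptv1", "min_dose", 70.0)
        plan = solve_weights(
            m, ph, [c], SolverOptions(max_iterations=300, tol=1e-12, initial_weight=1.0)
        )
        assert plan.weights[0] >= 139.9
        assert plan.dose[0] == pytest.approx(70.0, abs=0.05)

    def test_descent_from_uniform_start(self, default_phantom, imrt_matrix):
        c = OptimizationConstraint("c", "ptv1", "min_dose", 63.0)
        opts = SolverOptions(max_iterations=30, initial_weight=0.1)
        plan = solve_weights(imrt_matrix, default_phantom, [c], opts)
        f0 = total_objective(
            imrt_matrix.matrix @ np.full(imrt_matrix.n_beamlets, 0.1),
            default_phantom, [c],
        )[0]
        assert plan.objective_value < f0

    def test_satisfied_constraints_leave_weights_unchanged(self):
        ph = toy({"oar": [1, 1]}, 2, roles={"oar": "serial_oar"})
        m = make_toy_matrix([[0.5, 0.1], [0.2, 0.4]], (2,))
        c = OptimizationConstraint("c", "oar", "max_dose", 1000.0)
        w0 = np.array([3.0, 4.0])
        plan = solve_weights(m, ph, [c], SolverOptions(), warm_start=w0)
        assert np.array_equal(plan.weights, w0)
        assert plan.objective_value == 0.0

    def test_no_negative_weights(self):
        rng = np.random.default_rng(9)
        for trial in range(5):
            n_vox, n_b = 12, 6
            entries = rng.random((n_vox, n_b)) * (rng.random((n_vox, n_b)) < 0.5)
            ph = toy(
                {"ptv1": rng.random(n_vox) < 0.5, "oar": rng.random(n_vox) < 0.4},
                n_vox,
                roles={"oar": "serial_oar"},
            )
            if not ph.mask("ptv1").any() or not ph.mask("oar").any():
                continue
            m = make_toy_matrix(entries, (n_vox,))
            cs = [
                OptimizationConstraint("a", "ptv1", "min_dose", 60.0, weight=10),
                OptimizationConstraint("b", "oar", "max_dose", 5.0, weight=100),
            ]
            plan = solve_weights(m, ph, cs, SolverOptions(max_iterations=60,
                                                          initial_weight=1.0))
            assert (plan.weights >= 0).all()

    def test_objective_trace_monotone_within_rounds(self, default_phantom, imrt_matrix):
        cs = [
            OptimizationConstraint("a", "ptv1", "min_dvh", 66.5, volume_pct=95.0,
                                   weight=50),
            OptimizationConstraint("b", "body", "max_dose", 77.0, weight=10),
        ]
        plan = solve_weights(imrt_matrix, default_phantom, cs,
                             SolverOptions(max_iterations=60))
        bounds = plan.round_starts + [len(plan.obj_trace)]
        for lo, hi in zip(bounds, bounds[1:]):
            seg = plan.obj_trace[lo:hi]
            assert all(x >= y - 1e-12 for x, y in zip(seg, seg[1:]))

    def test_warm_start_wrong_length_rejected(self, default_phantom, imrt_matrix):
        c = OptimizationConstraint("c", "ptv1", "min_dose", 63.0)
        with pytest.raises(ValueError, match="length"):
            solve_weights(imrt_matrix, default_phantom, [c],
                          warm_start=np.ones(3))

    def test_deterministic(self, default_phantom, imrt_matrix):
        cs = [OptimizationConstraint("a", "ptv1", "uniform_dose", 70.0)]
        p1 = solve_weights(imrt_matrix, default_phantom, cs,
                           SolverOptions(max_iterations=40))
        p2 = solve_weights(imrt_matrix, default_phantom, cs,
                           SolverOptions(max_iterations=40))
        assert np.array_equal(p1.weights, p2.weights)
        assert p1.objective_value == p2.objective_value
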