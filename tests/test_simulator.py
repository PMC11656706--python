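"""Solver contracts: closed forms, convergence, grids, batching, scaling."""

import numpy as np
import pandas as pd
import pytest

from gutspulse._fast import fast_solve
from gutspulse.params import ScalingContext
from gutspulse.simulate import (
    ExposureScenario,
    batch_simulate,
    calibrate_scaling,
    compute_scaling,
    simulate,
)

PULSE = dict(k_i=0.5, k_m=0.3, z_ci=0.3, v_rt=10.0, r_rt=5.0, k_rd=2.0,
             k_p=0.03, z=2.0, k_k=0.05, h_b=5e-4)


def scenario(ce=5.0, tid="t1", substance="s"):
    return ExposureScenario(substance=substance, c_external=ce, treatment_id=tid)


class TestClosedForms:
    def test_control_treatment_stays_at_baseline(self):
        p = dict(PULSE, z_ci=0.5, v_rt=200.0, h_b=0.0)
        traj = simulate("guts_rna_pulse", p, ScalingContext(C_i_max=10.0),
                        scenario(ce=0.0))
        np.testing.assert_allclose(traj.S, 1.0, atol=1e-9)
        np.testing.assert_allclose(traj.states["C_i"], 0.0, atol=1e-9)
        np.testing.assert_allclose(traj.states["R"], 1.0, atol=1e-6)

    def test_linear_uptake_without_metabolization(self):
        p = dict(PULSE, k_m=0.0)
        t = np.linspace(1.0, 96.0, 30)
        traj = simulate("guts_rna_pulse", p, ScalingContext(C_i_max=300.0),
                        scenario(ce=5.0), t)
        np.testing.assert_allclose(
            traj.states["C_i"], p["k_i"] * 5.0 * t, rtol=1e-6
        )

    def test_reduced_one_compartment_closed_form(self):
        p = dict(k_d=0.08, z=10.0, k_k=0.1, h_b=0.0)
        t = np.linspace(0.5, 96.0, 30)
        traj = simulate("guts_reduced", p, None, scenario(ce=3.0), t)
        np.testing.assert_allclose(
            traj.states["D"], 3.0 * (1 - np.exp(-0.08 * t)), rtol=1e-6
        )

    def test_background_hazard_only_gives_exponential_survival(self):
        p = dict(PULSE, z=1e9, h_b=0.004)
        t = np.linspace(0.0, 96.0, 25)
        traj = simulate("guts_rna_pulse", p, ScalingContext(C_i_max=30.0),
                        scenario(), t)
        np.testing.assert_allclose(traj.S, np.exp(-0.004 * t), rtol=1e-6)


class TestSolverContracts:
    def test_tolerance_refinement_convergence(self):
        scaling = ScalingContext(C_i_max=30.0)
        t = np.linspace(0.0, 96.0, 49)
        a = simulate("guts_rna_pulse", PULSE, scaling, scenario(ce=20.0), t,
                     {"rtol": 1e-7, "atol": 1e-9})
        b = simulate("guts_rna_pulse", PULSE, scaling, scenario(ce=20.0), t,
                     {"rtol": 1e-8, "atol": 1e-10})
        for name in ("C_i", "R", "P_star"):
            denom = np.maximum(np.abs(b.states[name]), 1e-6)
            assert np.max(np.abs(a.states[name] - b.states[name]) / denom) < 1e-6

    def test_grid_invariance_dense_output(self):
        scaling = ScalingContext(C_i_max=30.0)
        fine = np.linspace(0.0, 96.0, 193)
        coarse = fine[::8]
        a = simulate("guts_rna_pulse", PULSE, scaling, scenario(ce=20.0), fine)
        b = simulate("guts_rna_pulse", PULSE, scaling, scenario(ce=20.0), coarse)
        for name, arr in b.states.items():
            np.testing.assert_allclose(arr, a.states[name][::8], rtol=1e-6,
                                       atol=1e-9)

    def test_trajectory_invariants_and_diagnostics(self):
        traj = simulate("guts_rna_pulse", PULSE, ScalingContext(C_i_max=30.0),
                        scenario(ce=20.0))
        traj.check_invariants()
        assert traj.diagnostics["solver_steps"] > 0

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError, match="t_grid"):
            simulate("guts_rna_pulse", PULSE, ScalingContext(C_i_max=30.0),
                     scenario(), np.array([0.0, 200.0]))

    def test_metabolization_overshoot_regime_is_stable(self):
        # strong feedback: fast protein turnover and metabolization
        p = dict(PULSE, k_m=5.0, k_p=1.0, r_rt=10.0)
        traj = simulate("guts_rna_pulse", p, ScalingContext(C_i_max=5.0),
                        scenario(ce=20.0))
        traj.check_invariants()

    def test_piecewise_exposure_restarts(self):
        sc = ExposureScenario(substance="s", treatment_id="pw",
                              c_external=[(0.0, 10.0), (24.0, 0.0)])
        t = np.linspace(0.0, 96.0, 97)
        traj = simulate("guts_rna_pulse", PULSE, ScalingContext(C_i_max=30.0),
                        sc, t)
        ci = traj.states["C_i"]
        assert ci[24] > 1.0
        assert ci[-1] < ci[24]  # decays after washout (metabolization only)


class TestFastPathAgreement:
    @pytest.mark.parametrize("variant,params", [
        ("guts_rna_pulse", PULSE),
        ("guts_reduced", dict(k_d=0.08, z=2.0, k_k=0.05, h_b=1e-3)),
        ("guts_scaled_damage",
         dict(k_i=0.5, k_e=0.05, k_d=0.1, z=20.0, k_k=0.002, h_b=1e-3)),
        ("guts_rna",
         dict(k_i=0.5, k_e=0.05, k_a=0.02, k_r=1.0, z=2.0, k_k=0.05, h_b=1e-3)),
    ])
    def test_batched_rk4_matches_adaptive_solver(self, variant, params):
        scaling = ScalingContext(C_i_max=30.0)
        t = np.linspace(1.0, 96.0, 20)
        sol = fast_solve(variant, params, np.array([5.0]), t, scaling, h=0.02)[0]
        traj = simulate(variant, params, scaling, scenario(ce=5.0), t)
        from gutspulse.params import get_variant

        for idx, name in enumerate(get_variant(variant).states):
            denom = np.maximum(np.abs(traj.states[name]), 1e-8)
            assert np.max(np.abs(sol[idx] - traj.states[name]) / denom) < 1e-3

    def test_infeasible_rates_yield_nan_not_crash(self):
        p = dict(PULSE, k_m=1e9, k_rd=1e-9, r_rt=1e9)
        sol = fast_solve("guts_rna_pulse", p, np.array([5.0]),
                         np.array([96.0]), ScalingContext(C_i_max=1.0))
        assert np.all(np.isnan(sol))


class TestBatchSimulate:
    def test_singleton_batch_equals_single_call(self):
        scaling = ScalingContext(C_i_max=30.0)
        sc = scenario(ce=5.0)
        single = simulate("guts_rna_pulse", PULSE, scaling, sc)
        batch = batch_simulate("guts_rna_pulse", {"s": PULSE}, [sc], scaling)
        assert len(batch) == 1
        np.testing.assert_array_equal(batch[0].states["C_i"], single.states["C_i"])

    def test_order_equivariance(self):
        scaling = ScalingContext(C_i_max=30.0)
        scens = [scenario(ce=c, tid=f"t{c}") for c in (1.0, 5.0, 20.0)]
        fwd = batch_simulate("guts_rna_pulse", {"s": PULSE}, scens, scaling)
        rev = batch_simulate("guts_rna_pulse", {"s": PULSE}, scens[::-1], scaling)
        np.testing.assert_array_equal(
            fwd[0].states["C_i"], rev[2].states["C_i"]
        )

    def test_missing_substance_block_named(self):
        with pytest.raises(KeyError, match="other"):
            batch_simulate("guts_rna_pulse", {"s": PULSE},
                           [scenario(substance="other")],
                           ScalingContext(C_i_max=30.0))

    def test_paper_scale_design_solves_without_failure(self):
        from gutspulse.synthetic import make_benchmark

        bundle = make_benchmark("paper_scale", seed=5)
        trajs = batch_simulate(
            "guts_rna_pulse", bundle.truth.params_by_substance,
            bundle.scenarios, bundle.truth.scaling,
            t_grid=np.linspace(0, 96, 13),
        )
        assert len(trajs) == len(bundle.scenarios) == 202
        for traj in trajs:
            traj.check_invariants()


class TestScaling:
    def test_compute_scaling_is_max_internal_concentration(self):
        df = pd.DataFrame({
            "treatment_id": ["a", "b", "c", "d"],
            "substance": ["s"] * 4,
            "endpoint": ["cint", "cint", "cint", "nrf2"],
            "time": [1.0, 2.0, 3.0, 4.0],
            "value": [2.0, 5.5, 1.1, 99.0],
            "n_at_risk": [np.nan] * 4,
            "c_external": [5.0] * 4,
        })
        scaling = compute_scaling(df)
        assert scaling.C_i_max == 5.5
        assert scaling.R_0 == 1.0

    def test_single_record(self):
        df = pd.DataFrame({
            "treatment_id": ["a"], "substance": ["s"], "endpoint": ["cint"],
            "time": [1.0], "value": [3.3], "n_at_risk": [np.nan],
            "c_external": [5.0],
        })
        assert compute_scaling(df).C_i_max == 3.3

    def test_no_concentration_records_rejected(self):
        df = pd.DataFrame({
            "treatment_id": ["a"], "substance": ["s"], "endpoint": ["nrf2"],
            "time": [1.0], "value": [1.0], "n_at_risk": [np.nan],
            "c_external": [5.0],
        })
        with pytest.raises(ValueError, match="C_i_max"):
            compute_scaling(df)

    def test_calibrated_scaling_is_self_consistent(self):
        scens = [scenario(ce=c, tid=f"t{c}") for c in (2.0, 20.0)]
        scaling = calibrate_scaling("guts_rna_pulse", {"s": PULSE}, scens)
        sol = fast_solve("guts_rna_pulse", PULSE, np.array([20.0]),
                         np.linspace(0, 96, 193), scaling, h=0.02)
        assert np.nanmax(sol[:, 0, :]) == pytest.approx(scaling.C_i_max, rel=0.02)
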