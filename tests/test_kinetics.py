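"""Kinetic model: production envelope, throttle flux, ODE solver."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tetrapulse import (Condition, KineticParams, production_rate,
                        simulate_cell, steady_state, tetramer_flux)
from tetrapulse.protocols import mean_rising_flux


class TestProductionRate:
    def test_pre_damage_and_zero_dose_return_baseline(self, params):
        assert production_rate(-10.0, 5.0, params) == params.beta0
        assert production_rate(500.0, 0.0, params) == params.beta0

    def test_piecewise_envelope_hand_values(self):
        p = KineticParams(beta0=0.0, beta1=1.0, tau0=120.0, tau1=20.0)
        # elevated until tau0 + tau1*dose = 240 min at dose 6
        assert production_rate(100.0, 6.0, p) == 6.0
        assert production_rate(300.0, 6.0, p) == 0.0

    def test_elevated_duration_increases_with_dose(self, params):
        # at t = 350 min dose 6 has relaxed (tau_end = 300) but dose 12 has not
        assert production_rate(350.0, 6.0, params) == params.beta0
        assert production_rate(350.0, 12.0, params) > params.beta0

    def test_negative_dose_rejected(self, params):
        with pytest.raises(ValueError):
            production_rate(10.0, -1.0, params)


class TestTetramerFlux:
    def test_no_substrate_no_flux(self, params):
        assert tetramer_flux(0.0, params) == 0.0

    def test_mass_action_limit(self):
        p = KineticParams(k_t=0.01)
        assert tetramer_flux(10.0, p, "knockdown") == pytest.approx(1.0)
        assert tetramer_flux(10.0, p.with_(K_A=math.inf)) == pytest.approx(1.0)

    def test_saturation_hand_value(self):
        p = KineticParams(k_t=0.01, K_A=1.0)
        assert tetramer_flux(10.0, p) == pytest.approx(0.01 * 100 / 101)

    @given(st.lists(st.floats(0, 1e4), min_size=2, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_bounded(self, ds):
        p = KineticParams(k_t=0.01, K_A=2.0)
        ds = sorted(ds)
        J = np.array([tetramer_flux(d, p) for d in ds])
        assert np.all(np.diff(J) >= -1e-12)
        for d, j in zip(ds, J):
            assert j <= p.k_t * min(d * d, p.K_A) + 1e-12


class TestSimulateCell:
    def test_null_dynamics(self):
        p = KineticParams(beta0=0.0, beta1=0.0)
        traj = simulate_cell(p, Condition(6.0), 240.0)
        assert np.all(traj.dimers == 0) and np.all(traj.tetramers == 0)
        assert np.allclose(traj.rfp, p.c_R) and np.allclose(traj.yfp, p.c)

    def test_sampling_grid(self, params):
        traj = simulate_cell(params, Condition(3.0), 480.0)
        assert np.allclose(traj.time, np.arange(0, 481, 15))
        assert np.all(np.isfinite(traj.rfp)) and np.all(traj.rfp >= 0)

    @pytest.mark.parametrize("genotype", ["L344P", "L344A", "M340E_L344K"])
    def test_mutants_form_no_tetramers(self, params, genotype):
        traj = simulate_cell(params, Condition(6.0, genotype=genotype), 480.0)
        assert np.all(traj.tetramers == 0)
        # YFP carries only bleed + offset
        expected = params.b * (traj.rfp - params.c_R) + params.c
        assert np.allclose(traj.yfp, expected)

    def test_mutant_background_ratio_is_genotype_independent(self, params):
        # dimeric and monomeric mutants are equally dark in YFP
        a = simulate_cell(params, Condition(6.0, genotype="L344A"), 480.0)
        b = simulate_cell(params, Condition(6.0, genotype="L344P"), 480.0)
        assert np.allclose(a.yfp, b.yfp)

    def test_non_divisible_duration_rejected(self, params):
        with pytest.raises(ValueError):
            simulate_cell(params, Condition(3.0), 100.0)

    def test_steady_state_initial_condition_is_stationary(self, params):
        p = params.with_(tau0=0.0, tau1=0.0)  # no elevated phase at dose 0
        traj = simulate_cell(p, Condition(0.0), 240.0)
        assert np.allclose(traj.dimers, traj.dimers[0], rtol=1e-6)
        assert np.allclose(traj.tetramers, traj.tetramers[0], rtol=1e-6)

    def test_steady_state_balances_production(self, params):
        D, Q = steady_state(params, Condition(0.0))
        J = tetramer_flux(float(D[0]), params)
        assert params.beta0 == pytest.approx(
            params.delta_D * float(D[0]) + 2 * J, rel=1e-9)
        assert float(Q[0]) == pytest.approx(J / params.delta_Q)


class TestSolverFidelity:
    def test_rk4_matches_finer_reference(self, params):
        cond = Condition(6.0)
        coarse = simulate_cell(params, cond, 240.0)
        fine = simulate_cell(params, cond, 240.0,
                             dt_solver=params.dt_solver / 20)
        for ch in ("rfp", "yfp"):
            a, b = getattr(coarse, ch), getattr(fine, ch)
            assert np.max(np.abs(a - b)) / np.max(np.abs(b)) < 1e-6

    def test_monomer_conservation_without_sources_and_sinks(self, params):
        p = params.with_(beta0=0.0, beta1=0.0, delta_D=0.0, delta_Q=0.0)
        traj = simulate_cell(p, Condition(6.0), 300.0, initial_state=(10.0, 1.0))
        total = 2 * traj.dimers + 4 * traj.tetramers
        assert np.max(np.abs(total - total[0])) / total[0] < 1e-9


class TestDoseResponseRegimes:
    def test_peak_total_p53_non_decreasing_in_dose(self, params):
        peaks = [simulate_cell(params, Condition(d), 1440.0).rfp.max()
                 for d in (0.0, 3.0, 6.0, 12.0)]
        assert np.all(np.diff(peaks) >= 0)

    def test_throttle_keeps_rising_flux_constant_but_knockdown_scales(self):
        on3, on12 = mean_rising_flux(3.0), mean_rising_flux(12.0)
        kd3, kd12 = (mean_rising_flux(3.0, "knockdown"),
                     mean_rising_flux(12.0, "knockdown"))
        assert abs(on12 - on3) / on3 < 0.10   # constant-rate regime
        assert kd12 / kd3 > 3.0               # flux tracks the input instead
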