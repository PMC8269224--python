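import math

import numpy as np
import pytest

from planoflux.dfba import (
    NORMAL,
    STARVATION,
    ConfigurationError,
    EnvironmentState,
    SimulationConfig,
    apply_regime,
    initial_state,
    simulate,
    step,
    uptake_bound,
)
from planoflux.model_core import FluxSolution
from planoflux.model_extension import REPLACEMENT_ID
from planoflux.priors import KineticParams
from planoflux.synthetic_data import ToyModelSpec, make_toy_model


def fast_switch_params():
    """Near-constant uptake bounds: tiny Km makes mu effectively constant,
    so the exponential-growth/phosphate-consumption closed form applies."""
    return KineticParams(
        vmax_glc=10.0, km_glc=1e-6,
        vmax_pi=10.0, km_pi=1e-6,
        vmax_ta=10.0, km_ta=0.015,
        vmax_o2=1000.0,
    )


def analytic_switch_time(spec: ToyModelSpec, mu: float, pi0: float,
                         threshold: float, x0: float) -> float:
    q = spec.p_per_gdw_total
    return math.log(1.0 + (pi0 - threshold) / (q * x0)) / mu


class TestUptakeBound:
    def test_half_saturation(self):
        assert uptake_bound(3.0, 10.0, 3.0) == pytest.approx(5.0)

    def test_no_substrate(self):
        assert uptake_bound(0.0, 10.0, 3.0) == 0.0

    def test_initial_glucose_bound(self):
        assert uptake_bound(222.2, 10.0, 3.0) == pytest.approx(
            222.2 * 10.0 / 225.2
        )

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            uptake_bound(-1.0, 10.0, 3.0)


class TestApplyRegime:
    @pytest.fixture()
    def state(self, toy_model):
        return initial_state(toy_model, SimulationConfig())

    def test_normal_regime_bounds(self, toy_model, state, reference_params):
        m = apply_regime(
            toy_model.copy(), state, reference_params, SimulationConfig()
        )
        assert m.reaction("EX_glc").lower_bound == pytest.approx(
            -uptake_bound(222.2, 10.0, 3.0)
        )
        assert m.reaction("EX_pi").lower_bound == pytest.approx(
            -uptake_bound(4.6, 0.13, 0.065)
        )
        assert m.reaction("EX_o2").lower_bound == -12.0
        assert m.reaction(REPLACEMENT_ID).upper_bound == 0.0
        assert m.objective_id == "BIOMASS"

    def test_starvation_blocks_phosphate_and_ta_synthesis(
        self, toy_model, state, reference_params
    ):
        state.regime = STARVATION
        m = apply_regime(
            toy_model.copy(), state, reference_params, SimulationConfig()
        )
        assert m.reaction("EX_pi").lower_bound == 0.0
        assert m.reaction("TA_SYNTH").upper_bound == 0.0
        assert m.objective_id == "BIOMASS_ALT"
        assert m.reaction("BIOMASS").upper_bound == 0.0

    def test_replacement_bound_at_half_saturation(
        self, toy_model, state, reference_params
    ):
        state.regime = STARVATION
        state.teichoic_pool = reference_params.km_ta
        m = apply_regime(
            toy_model.copy(), state, reference_params, SimulationConfig()
        )
        assert m.reaction(REPLACEMENT_ID).upper_bound == pytest.approx(
            reference_params.vmax_ta / 2.0
        )

    def test_unextended_model_rejected(self, chain_model, state,
                                       reference_params):
        with pytest.raises(ConfigurationError, match="extension"):
            apply_regime(chain_model, state, reference_params,
                         SimulationConfig())


class TestStep:
    def _state(self):
        return EnvironmentState(
            time=0.0, biomass=1.0,
            conc={"glc_e": 10.0, "pi_e": 1.0}, teichoic_pool=0.1,
        )

    def test_quiescent_fluxes_only_advance_time(self):
        sol = FluxSolution("optimal", 0.0, {})
        new = step(self._state(), sol, 0.5)
        assert new.time == 0.5
        assert new.biomass == 1.0
        assert new.conc == self._state().conc
        assert new.teichoic_pool == 0.1

    def test_biomass_forward_euler(self):
        sol = FluxSolution("optimal", 0.1, {})
        assert step(self._state(), sol, 1.0).biomass == pytest.approx(1.1)

    def test_glucose_forward_euler(self):
        sol = FluxSolution("optimal", 0.0, {"EX_glc": -5.0})
        new = step(self._state(), sol, 0.1)
        assert new.conc["glc_e"] == pytest.approx(9.5)

    def test_overshoot_clipped_to_zero(self):
        sol = FluxSolution("optimal", 0.0, {"EX_pi": -100.0})
        assert step(self._state(), sol, 0.5).conc["pi_e"] == 0.0

    def test_pool_balance(self):
        sol = FluxSolution(
            "optimal", 0.0, {"TA_SYNTH": 0.3, REPLACEMENT_ID: 0.1}
        )
        new = step(self._state(), sol, 1.0)
        assert new.teichoic_pool == pytest.approx(0.1 + 0.2)


class TestSimulate:
    def test_initial_pi_below_threshold_switches_at_zero(
        self, toy_model, reference_params
    ):
        cfg = SimulationConfig(pi0=0.05, t_end=1.0, dt=0.1)
        traj = simulate(toy_model, reference_params, cfg)
        assert traj.switch_time == 0.0
        assert traj.states[0].regime == STARVATION

    def test_huge_phosphate_never_switches(self, toy_model, reference_params):
        cfg = SimulationConfig(pi0=1e6, t_end=30.0, dt=0.5)
        traj = simulate(toy_model, reference_params, cfg)
        assert traj.switch_time is None
        assert all(s.regime == NORMAL for s in traj.states)

    def test_switch_time_matches_closed_form(self, toy_spec, toy_model):
        params = fast_switch_params()
        cfg = SimulationConfig(dt=0.1, t_end=10.0)
        traj = simulate(toy_model, params, cfg)
        mu0 = toy_spec.glucose_yield * params.vmax_glc
        t_star = analytic_switch_time(
            toy_spec, mu0, cfg.pi0, cfg.pi_threshold, cfg.biomass0
        )
        assert traj.switch_time is not None
        assert abs(traj.switch_time - t_star) <= 2.0 * cfg.dt

    def test_switch_time_monotone_in_initial_phosphate(self, toy_model):
        params = fast_switch_params()
        times = []
        for pi0 in (2.0, 4.6, 9.0):
            cfg = SimulationConfig(pi0=pi0, dt=0.1, t_end=15.0)
            times.append(simulate(toy_model, params, cfg).switch_time)
        assert all(t is not None for t in times)
        assert times[0] < times[1] < times[2]

    def test_monotone_state_variables(self, toy_model, reference_params):
        cfg = SimulationConfig(dt=0.25, t_end=25.0)
        traj = simulate(toy_model, reference_params, cfg)
        assert np.all(np.diff(traj.biomass) >= -1e-9)
        assert np.all(np.diff(traj.concentration("glc_e")) <= 1e-9)
        assert np.all(np.diff(traj.concentration("pi_e")) <= 1e-9)
        i_switch = int(round(traj.switch_time / cfg.dt))
        assert np.all(np.diff(traj.teichoic_pool[i_switch:]) <= 1e-9)

    def test_phosphorus_conserved(self, toy_spec, toy_model,
                                  reference_params):
        """Total P (extracellular + biomass-bound + wall pool) is constant
        up to Euler clipping error."""
        cfg = SimulationConfig(dt=0.1, t_end=22.0)
        traj = simulate(toy_model, reference_params, cfg)
        wall_p = toy_spec.polymer_units * toy_spec.phosphate_per_ta_unit
        total = (
            traj.concentration("pi_e")
            + traj.biomass * toy_spec.p_per_biomass
            + traj.teichoic_pool * wall_p
        )
        assert np.abs(total - total[0]).max() <= 10.0 * cfg.dt * 0.13

    def test_first_order_convergence_in_dt(self, toy_spec, toy_model):
        # no switch within the window: constant mu, analytic X0*exp(mu*t)
        params = fast_switch_params()
        mu = toy_spec.glucose_yield * params.vmax_glc
        errors = []
        for dt in (0.4, 0.2, 0.1):
            cfg = SimulationConfig(pi0=1e6, dt=dt, t_end=4.0)
            final = simulate(toy_model, params, cfg).biomass[-1]
            errors.append(abs(final - cfg.biomass0 * math.exp(mu * 4.0)))
        assert errors[2] < errors[1] < errors[0]
        # halving dt should roughly halve the error (first order)
        assert errors[2] / errors[1] == pytest.approx(0.5, abs=0.15)

    def test_replacement_closed_post_switch_stops_growth(
        self, toy_model, reference_params
    ):
        cfg = SimulationConfig(pi0=0.05, t_end=2.0, dt=0.1)
        # with a vanishing conversion Vmax the replacement reaction is
        # effectively closed, removing the only phosphate source post-switch
        params = KineticParams(
            **{**reference_params.as_dict(), "vmax_ta": 1e-12}
        )
        traj = simulate(toy_model, params, cfg)
        assert max(traj.growth_rates) <= 1e-6
        assert traj.biomass[-1] == pytest.approx(cfg.biomass0, rel=1e-6)

    def test_infeasible_steps_freeze_state(self, toy_model, reference_params):
        # no glucose at all: growth impossible, state carried forward
        cfg = SimulationConfig(glucose0=0.0, t_end=1.0, dt=0.25)
        traj = simulate(toy_model, reference_params, cfg)
        assert all(mu == pytest.approx(0.0, abs=1e-9)
                   for mu in traj.growth_rates)
        assert traj.biomass[-1] == cfg.biomass0

    def test_trajectory_frame_is_tidy(self, toy_model, reference_params):
        cfg = SimulationConfig(t_end=1.0, dt=0.5)
        frame = simulate(toy_model, reference_params, cfg).to_frame()
        assert list(frame["time"]) == [0.0, 0.5, 1.0]
        assert {"regime", "biomass", "teichoic_pool", "growth_rate",
                "glc_e", "pi_e"} <= set(frame.columns)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(dt=0.0)
        with pytest.raises(ConfigurationError):
            SimulationConfig(dt=1.0, t_end=0.5)
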