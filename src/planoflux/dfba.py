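"""Two-regime dynamic FBA with Michaelis-Menten uptake bounds.

The simulation alternates constraint updates and FBA solves on a fixed time
grid (static-optimization dFBA, forward Euler).  Two regimes are modelled:

* **normal growth** — glucose and phosphate uptake bounds follow
  Michaelis-Menten kinetics in the extracellular concentrations, O2 uptake
  is capped at a constant Vmax, wall teichoic acid is produced as part of
  biomass, and the wall-replacement reaction is closed;
* **phosphate starvation** — entered permanently at the first grid point
  where extracellular inorganic phosphate falls below a threshold
  (default 0.1 mmol/liter, the concentration at which the Pho regulon
  activates).  Phosphate uptake and teichoic-acid synthesis close, the
  alternative (teichuronic-wall) biomass becomes the objective, and the
  teichoic→teichuronic replacement reaction opens with a Michaelis-Menten
  bound evaluated at the accumulated teichoic-acid pool.

The teichoic-acid pool is carried in mmol polymer per liter of culture: it
is initialized as ``biomass0 × (biomass TA coefficient)``, grows with biomass
during normal growth, and is drawn down by the replacement reaction after
the switch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import FluxSolution, StoichiometricModel, solve_fba
from .model_extension import REPLACEMENT_ID
from .priors import KineticParams

__all__ = [
    "NORMAL",
    "STARVATION",
    "RegimeBindings",
    "SimulationConfig",
    "EnvironmentState",
    "Trajectory",
    "ConfigurationError",
    "uptake_bound",
    "apply_regime",
    "step",
    "simulate",
]

NORMAL = "normal"
STARVATION = "starvation"

_OPEN = 1000.0


class ConfigurationError(ValueError):
    """The simulation configuration does not match the model."""


@dataclass
class RegimeBindings:
    """Reaction/metabolite ids tying the regime logic to a concrete model.

    Defaults match the built-in toy model and the extension module's ids.
    """

    glucose_met: str = "glc_e"
    phosphate_met: str = "pi_e"
    glucose_exchange: str = "EX_glc"
    phosphate_exchange: str = "EX_pi"
    o2_exchange: str = "EX_o2"
    ta_exchange: str = "EX_ta"
    teichoic_met: str = "ta_e"
    ta_synthesis: str = "TA_SYNTH"
    replacement: str = REPLACEMENT_ID
    biomass: str = "BIOMASS"
    alternative_biomass: str = "BIOMASS_ALT"


@dataclass
class SimulationConfig:
    """Grid, initial conditions and regime threshold for a dFBA run.

    Concentrations are mmol/liter, biomass gDW/liter, times hours.
    """

    pi_threshold: float = 0.1
    t_end: float = 30.0
    dt: float = 0.05
    glucose0: float = 222.2
    pi0: float = 4.6
    biomass0: float = 0.5
    unconstrained_nutrients: list[str] = field(
        default_factory=lambda: ["EX_nh4"]
    )
    bindings: RegimeBindings = field(default_factory=RegimeBindings)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ConfigurationError("dt must be > 0")
        if self.t_end < self.dt:
            raise ConfigurationError("t_end must be >= dt")
        if self.pi_threshold < 0:
            raise ConfigurationError("pi_threshold must be >= 0")


@dataclass
class EnvironmentState:
    time: float
    biomass: float
    conc: dict[str, float]
    teichoic_pool: float
    regime: str = NORMAL

    def __post_init__(self) -> None:
        if self.biomass < 0 or self.teichoic_pool < 0:
            raise ValueError("biomass and teichoic_pool must be >= 0")
        if any(v < 0 for v in self.conc.values()):
            raise ValueError("concentrations must be >= 0")

    def copy(self) -> "EnvironmentState":
        return EnvironmentState(
            self.time, self.biomass, dict(self.conc),
            self.teichoic_pool, self.regime,
        )


@dataclass
class Trajectory:
    """States on a shared time grid plus per-step FBA summaries."""

    states: list[EnvironmentState]
    growth_rates: list[float]
    exchange_fluxes: list[dict[str, float]]
    switch_time: float | None = None

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.states])

    @property
    def biomass(self) -> np.ndarray:
        return np.array([s.biomass for s in self.states])

    @property
    def teichoic_pool(self) -> np.ndarray:
        return np.array([s.teichoic_pool for s in self.states])

    def concentration(self, met_id: str) -> np.ndarray:
        return np.array([s.conc[met_id] for s in self.states])

    def to_frame(self, bindings: RegimeBindings | None = None) -> pd.DataFrame:
        b = bindings or RegimeBindings()
        data = {
            "time": self.times,
            "regime": [s.regime for s in self.states],
            "biomass": self.biomass,
            "teichoic_pool": self.teichoic_pool,
            "growth_rate": np.array(self.growth_rates),
        }
        for met in self.states[0].conc:
            data[met] = self.concentration(met)
        for rid in (b.glucose_exchange, b.phosphate_exchange, b.o2_exchange):
            data[f"flux_{rid}"] = np.array(
                [fx.get(rid, 0.0) for fx in self.exchange_fluxes]
            )
        return pd.DataFrame(data)


def uptake_bound(conc: float, vmax: float, km: float) -> float:
    """Michaelis-Menten bound vmax*conc/(km+conc) on a substrate uptake rate."""
    if conc < 0:
        raise ValueError("concentration must be >= 0")
    if vmax <= 0 or km <= 0:
        raise ValueError("vmax and km must be > 0")
    return vmax * conc / (km + conc)


def _require_reactions(model: StoichiometricModel, ids: list[str]) -> None:
    missing = [i for i in ids if not model.has_reaction(i)]
    if missing:
        raise ConfigurationError(
            f"model lacks reactions required by the regime logic: {missing} "
            "(was the starvation extension applied?)"
        )


def apply_regime(
    model: StoichiometricModel,
    state: EnvironmentState,
    params: KineticParams,
    config: SimulationConfig,
) -> StoichiometricModel:
    """Set bounds and objective on ``model`` for the state's regime.

    Mutates and returns the passed model (callers owning the original should
    pass a copy).  Requires the starvation extension (alternative biomass,
    replacement reaction) to be present.
    """
    b = config.bindings
    _require_reactions(
        model,
        [
            b.glucose_exchange, b.phosphate_exchange, b.o2_exchange,
            b.ta_exchange, b.ta_synthesis, b.replacement,
            b.biomass, b.alternative_biomass,
        ],
    )
    glc = state.conc[b.glucose_met]
    pi = state.conc[b.phosphate_met]

    model.reaction(b.glucose_exchange).lower_bound = -uptake_bound(
        glc, params.vmax_glc, params.km_glc
    )
    model.reaction(b.o2_exchange).lower_bound = -params.vmax_o2
    for rid in config.unconstrained_nutrients:
        model.reaction(rid).lower_bound = -_OPEN

    biomass = model.reaction(b.biomass)
    alt = model.reaction(b.alternative_biomass)
    ta_synth = model.reaction(b.ta_synthesis)
    replacement = model.reaction(b.replacement)
    ex_ta = model.reaction(b.ta_exchange)
    ex_pi = model.reaction(b.phosphate_exchange)

    if state.regime == NORMAL:
        ex_pi.lower_bound = -uptake_bound(pi, params.vmax_pi, params.km_pi)
        ta_synth.lower_bound, ta_synth.upper_bound = 0.0, _OPEN
        replacement.lower_bound, replacement.upper_bound = 0.0, 0.0
        ex_ta.lower_bound, ex_ta.upper_bound = 0.0, 0.0
        biomass.lower_bound, biomass.upper_bound = 0.0, _OPEN
        alt.lower_bound, alt.upper_bound = 0.0, 0.0
        model.objective_id = b.biomass
    else:
        ex_pi.lower_bound = 0.0
        ta_synth.lower_bound, ta_synth.upper_bound = 0.0, 0.0
        replacement.lower_bound = 0.0
        replacement.upper_bound = uptake_bound(
            state.teichoic_pool, params.vmax_ta, params.km_ta
        ) if state.teichoic_pool > 0 else 0.0
        ex_ta.lower_bound, ex_ta.upper_bound = -_OPEN, 0.0
        biomass.lower_bound, biomass.upper_bound = 0.0, 0.0
        alt.lower_bound, alt.upper_bound = 0.0, _OPEN
        model.objective_id = b.alternative_biomass
    return model


def step(
    state: EnvironmentState,
    solution: FluxSolution,
    dt: float,
    bindings: RegimeBindings | None = None,
) -> EnvironmentState:
    """Forward-Euler update of biomass, tracked pools and the TA reserve.

    Tracked extracellular metabolites are advanced with their exchange
    fluxes (``EX_<...>`` per ``bindings``).  If a pool would overshoot
    below zero, the whole step's fluxes are rescaled so the limiting pool
    is exhausted exactly — growth and every coupled pool shrink together,
    which keeps elemental bookkeeping exact at depletion instead of
    conjuring mass out of the clip.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    b = bindings or RegimeBindings()
    mu = solution.objective_value if solution.optimal else 0.0
    X = state.biomass

    exchange_of = {
        b.glucose_met: b.glucose_exchange,
        b.phosphate_met: b.phosphate_exchange,
    }
    deltas: dict[str, float] = {}
    for met in state.conc:
        rid = exchange_of.get(met, f"EX_{met}")
        deltas[met] = solution.fluxes.get(rid, 0.0) * X * dt
    v_synth = solution.fluxes.get(b.ta_synthesis, 0.0)
    v_repl = solution.fluxes.get(b.replacement, 0.0)
    pool_delta = (v_synth - v_repl) * X * dt

    # limiting-substrate rescale: the largest lam in [0, 1] keeping all
    # pools nonnegative
    lam = 1.0
    for met, d in deltas.items():
        if state.conc[met] + d < 0.0:
            lam = min(lam, state.conc[met] / -d)
    if state.teichoic_pool + pool_delta < 0.0:
        lam = min(lam, state.teichoic_pool / -pool_delta)

    new = state.copy()
    new.time = state.time + dt
    new.biomass = X * (1.0 + mu * dt * lam)
    for met, d in deltas.items():
        new.conc[met] = max(0.0, state.conc[met] + d * lam)
    new.teichoic_pool = max(0.0, state.teichoic_pool + pool_delta * lam)
    return new


def initial_state(
    model: StoichiometricModel, config: SimulationConfig
) -> EnvironmentState:
    """Build the t=0 state; the TA pool starts at biomass0 × TA coefficient."""
    b = config.bindings
    biomass = model.reaction(b.biomass)
    ta_coeff = -biomass.stoichiometry.get(b.teichoic_met, 0.0)
    return EnvironmentState(
        time=0.0,
        biomass=config.biomass0,
        conc={b.glucose_met: config.glucose0, b.phosphate_met: config.pi0},
        teichoic_pool=config.biomass0 * max(ta_coeff, 0.0),
        regime=NORMAL,
    )


def simulate(
    model: StoichiometricModel,
    params: KineticParams,
    config: SimulationConfig | None = None,
) -> Trajectory:
    """Run the two-regime dFBA on the fixed grid and return the trajectory.

    The switch to starvation happens permanently at the first grid point
    with ``[pi] < pi_threshold`` (t=0 included).  An infeasible FBA step
    contributes zero growth and carries the state forward unchanged.
    """
    config = config or SimulationConfig()
    b = config.bindings
    work = model.copy()
    state = initial_state(work, config)

    n_steps = int(round(config.t_end / config.dt))
    states: list[EnvironmentState] = []
    growth: list[float] = []
    fluxes: list[dict[str, float]] = []
    switch_time: float | None = None

    key_rxns = [
        b.glucose_exchange, b.phosphate_exchange, b.o2_exchange,
        b.ta_synthesis, b.replacement,
    ]

    for k in range(n_steps + 1):
        if (
            switch_time is None
            and state.conc[b.phosphate_met] < config.pi_threshold
        ):
            switch_time = state.time
        if switch_time is not None:
            state.regime = STARVATION

        apply_regime(work, state, params, config)
        sol = solve_fba(work)
        mu = sol.objective_value if sol.optimal else 0.0

        states.append(state.copy())
        growth.append(mu)
        fluxes.append({rid: sol.fluxes.get(rid, 0.0) for rid in key_rxns})

        if k < n_steps:
            state = step(state, sol, config.dt, b)

    return Trajectory(
        states=states, growth_rates=growth,
        exchange_fluxes=fluxes, switch_time=switch_time,
    )
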