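import pytest

from planoflux.model_core import (
    Metabolite,
    Reaction,
    StoichiometricModel,
)
from planoflux.priors import KineticParams
from planoflux.synthetic_data import ToyModelSpec, make_toy_model

TOY_SPEC = ToyModelSpec()


@pytest.fixture(scope="session")
def toy_spec():
    return TOY_SPEC


@pytest.fixture(scope="session")
def toy_model():
    """The extended toy starvation model (shared read-only; copy to mutate)."""
    return make_toy_model(TOY_SPEC)


@pytest.fixture()
def chain_model():
    """Hand-solvable linear chain: glucose uptake <= 10, biomass yield 0.5.

    glc_e --(EX, lb -10)--> glc_c --(0.5 gDW per mmol)--> growth
    """
    return StoichiometricModel(
        metabolites=[
            Metabolite(id="glc_e", compartment="e"),
            Metabolite(id="glc_c", compartment="c"),
        ],
        reactions=[
            Reaction(id="EX_glc", stoichiometry={"glc_e": -1.0},
                     lower_bound=-10.0, upper_bound=1000.0),
            Reaction(id="T_glc", stoichiometry={"glc_e": -1.0, "glc_c": 1.0},
                     upper_bound=1000.0),
            Reaction(id="GROWTH", stoichiometry={"glc_c": -2.0},
                     upper_bound=1000.0),
        ],
        objective_id="GROWTH",
    )


@pytest.fixture(scope="session")
def reference_params():
    """One mid-prior kinetic parameter set (the printed central values)."""
    return KineticParams(
        vmax_glc=10.0, km_glc=3.0,
        vmax_pi=0.13, km_pi=0.065,
        vmax_ta=10.0, km_ta=0.015,
        vmax_o2=12.0,
    )
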