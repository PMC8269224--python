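"""Phosphate-starvation machinery for a stoichiometric model.

Under phosphate limitation many Gram-positive bacteria stop making wall
teichoic acid (a phosphate-rich polymer) and build phosphate-free
teichuronic acid instead, scavenging the phosphodiester phosphate of the
existing wall.  These operations retrofit that physiology onto any model
that carries the UDP-sugar precursors:

* a UDP-N-acetylglucosamine 4-epimerase (galE-type, gene EV45_RS04840) and a
  teichuronate synthase building a polymer of N-acetylgalactosamine and
  d-glucuronate in equal proportions (default 25 repeat units);
* an alternative biomass reaction in which the teichoic-acid term is swapped
  for an equimolar teichuronic-acid term;
* a replacement reaction converting one wall teichoic-acid polymer into one
  teichuronic-acid polymer, releasing its phosphate as inorganic phosphate
  (the dephosphorylated backbone leaves through a dedicated sink so mass
  balance is preserved);
* a lumped secondary-metabolite reaction (one global step plus an exchange)
  for products whose pathway is not resolved.

All operations are idempotent and phosphorus-balanced whenever the involved
metabolites carry phosphorus counts.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model_core import (
    EXTRACELLULAR,
    Metabolite,
    Reaction,
    StoichiometricModel,
    phosphorus_imbalance,
)

__all__ = [
    "ExtensionSpec",
    "ExtensionError",
    "add_teichuronate_pathway",
    "make_alternative_biomass",
    "add_replacement_reaction",
    "add_lumped_product",
    "extend_model",
    "EPIMERASE_ID",
    "TUA_SYNTH_ID",
    "REPLACEMENT_ID",
    "BACKBONE_SINK_ID",
    "TUA_DEMAND_ID",
]

EPIMERASE_ID = "UDPGLCNAC_EPIM"
TUA_SYNTH_ID = "TUA_SYNTH"
REPLACEMENT_ID = "TA_REPLACEMENT"
BACKBONE_SINK_ID = "SK_ta_backbone"
TUA_DEMAND_ID = "DM_tua"
EPIMERASE_GENE = "EV45_RS04840"


class ExtensionError(ValueError):
    """A model lacks a prerequisite for an extension operation."""


@dataclass
class ExtensionSpec:
    """Names and stoichiometric conventions for the starvation extension.

    ``polymer_units`` is the number of repeat units per wall polymer;
    ``phosphate_per_ta_unit`` the phosphodiester P atoms released per
    teichoic-acid repeat unit (1 for a glycerol/ribitol-phosphate wall).
    """

    biomass_id: str = "BIOMASS"
    teichoic_met_id: str = "ta_e"
    teichuronic_met_id: str = "tua_c"
    polymer_units: int = 25
    phosphate_per_ta_unit: int = 1
    udp_glcnac_id: str = "udp_glcnac_c"
    udp_glcur_id: str = "udp_glcur_c"
    udp_galnac_id: str = "udp_galnac_c"
    udp_id: str = "udp_c"
    phosphate_met_id: str = "pi_c"
    backbone_met_id: str = "ta_backbone_c"
    alternative_biomass_id: str = "BIOMASS_ALT"

    def __post_init__(self) -> None:
        if self.polymer_units < 1:
            raise ValueError("polymer_units must be >= 1")
        if self.phosphate_per_ta_unit < 0:
            raise ValueError("phosphate_per_ta_unit must be >= 0")


def _require_metabolites(model: StoichiometricModel, ids: list[str]) -> None:
    missing = [i for i in ids if not model.has_metabolite(i)]
    if missing:
        raise ExtensionError(f"model lacks required metabolites: {missing}")


def _add_reaction_idempotent(
    model: StoichiometricModel, rxn: Reaction
) -> bool:
    """Add ``rxn`` unless an identical one is present.  Returns True if added."""
    if model.has_reaction(rxn.id):
        existing = model.reaction(rxn.id)
        if existing.stoichiometry != rxn.stoichiometry:
            raise ExtensionError(
                f"reaction {rxn.id} already exists with different "
                "stoichiometry"
            )
        return False
    model.reactions.append(rxn)
    return True


def _assert_p_balanced(model: StoichiometricModel, rxn_id: str) -> None:
    imb = phosphorus_imbalance(model, model.reaction(rxn_id))
    if imb is not None and abs(imb) > 1e-9:
        raise ExtensionError(
            f"added reaction {rxn_id} is phosphorus-imbalanced ({imb:+g} P)"
        )


def add_teichuronate_pathway(
    model: StoichiometricModel, spec: ExtensionSpec
) -> StoichiometricModel:
    """Add the epimerase and the teichuronate synthase.

    The synthase consumes ``polymer_units`` each of UDP-N-acetylgalactosamine
    and UDP-d-glucuronate per polymer (equal proportions) and releases the
    UDP moieties.  UDP-N-acetylgalactosamine is produced only by the
    epimerase, as in the galE logic.
    """
    model = model.copy()
    _require_metabolites(model, [spec.udp_glcnac_id, spec.udp_glcur_id])
    # UDP sugars carry the 2 P of the UDP moiety
    for met_id, name, p in [
        (spec.udp_galnac_id, "UDP-N-acetylgalactosamine", 2),
        (spec.udp_id, "UDP", 2),
        (spec.teichuronic_met_id, "teichuronic acid polymer", 0),
    ]:
        if not model.has_metabolite(met_id):
            model.metabolites.append(
                Metabolite(id=met_id, name=name, phosphorus_count=p)
            )
    u = spec.polymer_units
    _add_reaction_idempotent(
        model,
        Reaction(
            id=EPIMERASE_ID,
            name="UDP-N-acetylglucosamine 4-epimerase",
            stoichiometry={spec.udp_glcnac_id: -1.0, spec.udp_galnac_id: 1.0},
            lower_bound=-1000.0,
            upper_bound=1000.0,
            gene_rule=EPIMERASE_GENE,
        ),
    )
    _add_reaction_idempotent(
        model,
        Reaction(
            id=TUA_SYNTH_ID,
            name="teichuronate synthase",
            stoichiometry={
                spec.udp_galnac_id: -float(u),
                spec.udp_glcur_id: -float(u),
                spec.teichuronic_met_id: 1.0,
                spec.udp_id: 2.0 * u,
            },
            lower_bound=0.0,
            upper_bound=1000.0,
        ),
    )
    for rid in (EPIMERASE_ID, TUA_SYNTH_ID):
        _assert_p_balanced(model, rid)
    model.validate()
    return model


def make_alternative_biomass(
    model: StoichiometricModel, spec: ExtensionSpec
) -> StoichiometricModel:
    """Clone the biomass reaction with teichuronic acid in place of teichoic.

    The polymer coefficient is carried over unchanged (equal polymer count);
    the clone is created closed — regime control decides which biomass is
    open.  The original biomass reaction is untouched.
    """
    model = model.copy()
    if not model.has_reaction(spec.biomass_id):
        raise ExtensionError(f"biomass reaction {spec.biomass_id!r} not found")
    biomass = model.reaction(spec.biomass_id)
    ta_coeff = biomass.stoichiometry.get(spec.teichoic_met_id, 0.0)
    if ta_coeff >= 0.0:
        raise ExtensionError(
            f"biomass {spec.biomass_id} does not consume "
            f"{spec.teichoic_met_id}"
        )
    if not model.has_metabolite(spec.teichuronic_met_id):
        raise ExtensionError(
            f"model lacks {spec.teichuronic_met_id}; apply "
            "add_teichuronate_pathway first"
        )
    stoich = dict(biomass.stoichiometry)
    del stoich[spec.teichoic_met_id]
    stoich[spec.teichuronic_met_id] = ta_coeff
    _add_reaction_idempotent(
        model,
        Reaction(
            id=spec.alternative_biomass_id,
            name=biomass.name + " (teichuronic wall)" if biomass.name else "",
            stoichiometry=stoich,
            lower_bound=0.0,
            upper_bound=0.0,
        ),
    )
    model.validate()
    return model


def add_replacement_reaction(
    model: StoichiometricModel, spec: ExtensionSpec
) -> StoichiometricModel:
    """Add the teichoic→teichuronic wall replacement reaction.

    One teichoic-acid polymer plus the UDP-sugar precursors of one
    teichuronic polymer yield one teichuronic polymer, releasing
    ``polymer_units * phosphate_per_ta_unit`` inorganic phosphate and the
    dephosphorylated backbone (removed through a sink).  Irreversible and
    created closed; the starvation regime opens it with a kinetic bound.
    """
    model = model.copy()
    _require_metabolites(
        model,
        [
            spec.teichoic_met_id,
            spec.teichuronic_met_id,
            spec.udp_galnac_id,
            spec.udp_glcur_id,
            spec.phosphate_met_id,
        ],
    )
    if not model.has_metabolite(spec.backbone_met_id):
        model.metabolites.append(
            Metabolite(
                id=spec.backbone_met_id,
                name="dephosphorylated teichoic-acid backbone",
                phosphorus_count=0,
            )
        )
    u = spec.polymer_units
    p_released = float(u * spec.phosphate_per_ta_unit)
    stoich = {
        spec.teichoic_met_id: -1.0,
        spec.udp_galnac_id: -float(u),
        spec.udp_glcur_id: -float(u),
        spec.teichuronic_met_id: 1.0,
        spec.udp_id: 2.0 * u,
        spec.backbone_met_id: 1.0,
    }
    if p_released > 0:
        stoich[spec.phosphate_met_id] = p_released
    _add_reaction_idempotent(
        model,
        Reaction(
            id=REPLACEMENT_ID,
            name="teichoic to teichuronic acid replacement",
            stoichiometry=stoich,
            lower_bound=0.0,
            upper_bound=0.0,
        ),
    )
    _add_reaction_idempotent(
        model,
        Reaction(
            id=BACKBONE_SINK_ID,
            name="teichoic-acid backbone sink",
            stoichiometry={spec.backbone_met_id: -1.0},
            lower_bound=0.0,
            upper_bound=1000.0,
        ),
    )
    # teichuronic polymer built into the pre-existing wall (rather than new
    # biomass) leaves through a demand reaction; it carries no phosphorus
    _add_reaction_idempotent(
        model,
        Reaction(
            id=TUA_DEMAND_ID,
            name="wall-retained teichuronic acid demand",
            stoichiometry={spec.teichuronic_met_id: -1.0},
            lower_bound=0.0,
            upper_bound=1000.0,
        ),
    )
    _assert_p_balanced(model, REPLACEMENT_ID)
    model.validate()
    return model


def add_lumped_product(
    model: StoichiometricModel,
    product_id: str,
    precursor_stoichiometry: dict[str, float],
    reaction_id: str | None = None,
) -> StoichiometricModel:
    """Add a single global biosynthesis reaction and an exchange for a product
    whose pathway is not resolved reaction-by-reaction.

    ``precursor_stoichiometry`` maps precursor metabolite ids to the (positive)
    number of units consumed per product.
    """
    if not precursor_stoichiometry:
        raise ExtensionError("lumped product needs at least one precursor")
    if any(v <= 0 for v in precursor_stoichiometry.values()):
        raise ExtensionError("precursor coefficients must be positive")
    model = model.copy()
    _require_metabolites(model, list(precursor_stoichiometry))
    if not model.has_metabolite(product_id):
        model.metabolites.append(
            Metabolite(
                id=product_id,
                name=product_id,
                compartment=EXTRACELLULAR,
                phosphorus_count=0,
            )
        )
    stoich = {k: -float(v) for k, v in precursor_stoichiometry.items()}
    stoich[product_id] = 1.0
    rid = reaction_id or f"LUMP_{product_id}"
    _add_reaction_idempotent(
        model,
        Reaction(
            id=rid,
            name=f"lumped biosynthesis of {product_id}",
            stoichiometry=stoich,
            lower_bound=0.0,
            upper_bound=1000.0,
        ),
    )
    _add_reaction_idempotent(
        model,
        Reaction(
            id=f"EX_{product_id}",
            name=f"{product_id} exchange",
            stoichiometry={product_id: -1.0},
            lower_bound=0.0,
            upper_bound=1000.0,
        ),
    )
    model.validate()
    return model


def extend_model(
    model: StoichiometricModel, spec: ExtensionSpec
) -> StoichiometricModel:
    """Apply the full starvation extension (pathway, biomass, replacement)."""
    model = add_teichuronate_pathway(model, spec)
    model = make_alternative_biomass(model, spec)
    model = add_replacement_reaction(model, spec)
    return model
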