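"""Self-contained generators for every input the pipeline consumes.

Three generators:

* ``make_toy_model`` — a ~20-reaction, mass-balanced (in phosphorus)
  genome-scale-model stand-in with glucose/phosphate/O2/ammonium
  exchanges, a teichoic-acid-containing biomass, UDP-sugar precursor
  supply, and the full starvation extension.  Its stoichiometry is chosen
  so growth and switch-time behaviour have closed forms (see below), which
  the test suite exploits.
* ``make_synthetic_counts`` — negative-binomial count matrices over the
  five-time-point × three-replicate fermentation design with planted
  cluster-specific temporal archetypes and optional null (flat) features.
* ``make_ranked_group`` — ranked lists with a planted enriched group for
  the iGA statistic.

Toy-model arithmetic (defaults): the biomass reaction consumes
``1/glucose_yield`` precursor, ``p_per_biomass`` phosphate and ``ta_coeff``
teichoic-acid polymer per gDW.  Catabolism converts 1 glucose + 1 O2 +
0.2 ammonium into 1 precursor, so when glucose uptake v_glc binds,
mu* = glucose_yield * v_glc.  Net phosphate drain per gDW grown is
q_P = p_per_biomass + ta_coeff * polymer_units (wall phosphate included),
so under constant mu exponential growth depletes phosphate from pi0 to a
threshold at

    t* = (1/mu) * ln(1 + (pi0 - threshold) / (q_P * X0)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import (
    CYTOSOL,
    EXTRACELLULAR,
    Metabolite,
    Reaction,
    StoichiometricModel,
)
from .model_extension import ExtensionSpec, add_lumped_product, extend_model
from .omics_stats import RankedGroup

__all__ = [
    "ToyModelSpec",
    "OmicsSimSpec",
    "make_toy_model",
    "make_synthetic_counts",
    "make_ranked_group",
    "ARCHETYPES",
]


# ---------------------------------------------------------------------------
# Toy genome-scale model
# ---------------------------------------------------------------------------

@dataclass
class ToyModelSpec:
    """Stoichiometric knobs of the toy network (all strictly positive).

    glucose_yield: gDW biomass per mmol glucose (sets mu when C-limited).
    p_per_biomass: mmol non-wall P per gDW (nucleic acids, phospholipids).
    ta_coeff: mmol teichoic-acid polymer per gDW of biomass.
    """

    glucose_yield: float = 0.05
    p_per_biomass: float = 0.8
    ta_coeff: float = 0.008
    polymer_units: int = 25
    phosphate_per_ta_unit: int = 1
    include_product: bool = True

    def __post_init__(self) -> None:
        for name in ("glucose_yield", "p_per_biomass", "ta_coeff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.polymer_units < 1:
            raise ValueError("polymer_units must be >= 1")
        if self.phosphate_per_ta_unit < 0:
            raise ValueError("phosphate_per_ta_unit must be >= 0")

    def extension_spec(self) -> ExtensionSpec:
        return ExtensionSpec(
            polymer_units=self.polymer_units,
            phosphate_per_ta_unit=self.phosphate_per_ta_unit,
        )

    @property
    def p_per_gdw_total(self) -> float:
        """Total P drain per gDW grown in normal regime (wall included)."""
        return (
            self.p_per_biomass
            + self.ta_coeff * self.polymer_units * self.phosphate_per_ta_unit
        )


def make_toy_model(spec: ToyModelSpec | None = None) -> StoichiometricModel:
    """Build the toy model and apply the full starvation extension.

    Static default bounds: glucose uptake capped at 10 mmol/gDW/h, all other
    exchanges open at 1000 — so plain FBA growth is glucose-limited and
    equals ``glucose_yield * 10`` exactly.  The dFBA regime logic overrides
    these bounds each step.
    """
    spec = spec or ToyModelSpec()
    u = spec.polymer_units

    def met(mid, name, comp=CYTOSOL, p=0):
        return Metabolite(id=mid, name=name, compartment=comp,
                          phosphorus_count=p)

    mets = [
        met("glc_e", "glucose", EXTRACELLULAR),
        met("pi_e", "inorganic phosphate", EXTRACELLULAR, 1),
        met("o2_e", "oxygen", EXTRACELLULAR),
        met("nh4_e", "ammonium", EXTRACELLULAR),
        met("ta_e", "wall teichoic acid polymer", EXTRACELLULAR,
            u * spec.phosphate_per_ta_unit),
        met("glc_c", "glucose (cytosol)"),
        met("pi_c", "inorganic phosphate (cytosol)", p=1),
        met("o2_c", "oxygen (cytosol)"),
        met("nh4_c", "ammonium (cytosol)"),
        met("prec_c", "generic biomass precursor"),
        met("udp_glcnac_c", "UDP-N-acetylglucosamine", p=2),
        met("udp_glcur_c", "UDP-d-glucuronate", p=2),
        met("udp_c", "UDP", p=2),
        met("aa1_c", "amino-acid pool 1"),
        met("aa2_c", "amino-acid pool 2"),
    ]

    def rxn(rid, stoich, lb=0.0, ub=1000.0, gene="", name=""):
        return Reaction(id=rid, stoichiometry=stoich, lower_bound=lb,
                        upper_bound=ub, gene_rule=gene, name=name)

    # biomass precursor share is net of the wall polymer's precursor cost,
    # so total glucose demand per gDW is exactly 1/glucose_yield and the
    # glucose-limited growth rate is glucose_yield * v_glc in closed form
    prec_per_gdw = 1.0 / spec.glucose_yield - spec.ta_coeff * u
    if prec_per_gdw <= 0:
        raise ValueError(
            "glucose_yield too large for the wall cost: need "
            "1/glucose_yield > ta_coeff * polymer_units"
        )
    rxns = [
        rxn("EX_glc", {"glc_e": -1.0}, lb=-10.0),
        rxn("EX_pi", {"pi_e": -1.0}, lb=-1000.0),
        rxn("EX_o2", {"o2_e": -1.0}, lb=-1000.0),
        rxn("EX_nh4", {"nh4_e": -1.0}, lb=-1000.0),
        # wall teichoic-acid pool boundary; closed during normal growth
        rxn("EX_ta", {"ta_e": -1.0}, lb=0.0, ub=0.0),
        rxn("T_glc", {"glc_e": -1.0, "glc_c": 1.0}, gene="g_ptsG"),
        rxn("T_pi", {"pi_e": -1.0, "pi_c": 1.0}, gene="g_pstS"),
        rxn("T_o2", {"o2_e": -1.0, "o2_c": 1.0}),
        rxn("T_nh4", {"nh4_e": -1.0, "nh4_c": 1.0}, gene="g_amtB"),
        # lumped aerobic catabolism + anabolic precursor supply
        rxn(
            "CATAB",
            {"glc_c": -1.0, "o2_c": -1.0, "nh4_c": -0.2, "prec_c": 1.0},
            gene="g_glyc and g_tca",
        ),
        rxn("UDP_GLCNAC_SYN",
            {"prec_c": -1.0, "pi_c": -2.0, "udp_glcnac_c": 1.0}),
        rxn("UDP_GLCUR_SYN",
            {"prec_c": -1.0, "pi_c": -2.0, "udp_glcur_c": 1.0}),
        # wall teichoic acid: u repeat units, phosphate_per_ta_unit P each
        rxn(
            "TA_SYNTH",
            (
                {"prec_c": -float(u), "ta_e": 1.0}
                if spec.phosphate_per_ta_unit == 0
                else {
                    "pi_c": -float(u * spec.phosphate_per_ta_unit),
                    "prec_c": -float(u),
                    "ta_e": 1.0,
                }
            ),
            gene="g_tagO",
        ),
        # keeps the UDP moiety's phosphate in the cytosolic pi pool
        rxn("UDP_RECYCLE", {"udp_c": -1.0, "pi_c": 2.0}),
        rxn("AA1_SYN", {"prec_c": -1.0, "aa1_c": 1.0}),
        rxn("AA2_SYN", {"prec_c": -1.0, "aa2_c": 1.0}),
        rxn(
            "BIOMASS",
            {
                "prec_c": -prec_per_gdw,
                "pi_c": -spec.p_per_biomass,
                "ta_e": -spec.ta_coeff,
            },
            name="biomass (teichoic wall)",
        ),
    ]
    model = StoichiometricModel(
        metabolites=mets, reactions=rxns, objective_id="BIOMASS",
        annotations={"id": "toy_starvation_model"},
    )
    model = extend_model(model, spec.extension_spec())
    if spec.include_product:
        model = add_lumped_product(
            model, "ge2270a_e", {"aa1_c": 3.0, "aa2_c": 5.0},
            reaction_id="LUMP_ge2270a",
        )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Synthetic omics matrices
# ---------------------------------------------------------------------------

#: eight temporal archetypes over five time points (relative log2 shapes).
#: Chosen mutually well separated after per-profile z-scoring (minimum
#: pairwise distance ~1.2 in z-space) so the shapes stay distinguishable
#: at realistic count noise.
ARCHETYPES = (
    np.array(
        [
            [2, 1, 0, -1, -2],    # monotone decline
            [-2, -1, 0, 1, 2],    # monotone rise
            [-2, 1, 2, 1, -2],    # mid-course peak
            [2, -1, -2, -1, 2],   # mid-course valley
            [1, -2, 0, 2, -1],    # dip then late peak
            [-1, 2, 0, -2, 1],    # early peak then late recovery
            [2, 2, -1, -2, -1],   # sustained start, late repression
            [-2, -2, 1, 2, 1],    # delayed induction, sustained end
        ],
        dtype=float,
    )
    / 4.0
    + 0.5
)


@dataclass
class OmicsSimSpec:
    """Design of the synthetic time-course count matrix."""

    n_features: int = 400
    k_clusters: int = 8
    timepoints: tuple = (15, 24, 39, 48, 63)
    replicates: int = 3
    base_mean: float = 200.0
    amplitude: float = 3.0        # log2 dynamic range of the archetypes
    dispersion: float = 0.1       # NB dispersion; var = m + disp * m^2
    fraction_null: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_clusters > self.n_features:
            raise ValueError("k_clusters must not exceed n_features")
        if self.k_clusters > ARCHETYPES.shape[0]:
            raise ValueError(
                f"at most {ARCHETYPES.shape[0]} archetypes are defined"
            )
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if not 0 <= self.fraction_null <= 1:
            raise ValueError("fraction_null must be in [0, 1]")


def make_synthetic_counts(spec: OmicsSimSpec | None = None):
    """Negative-binomial counts with planted temporal cluster structure.

    Returns ``(counts, lengths, groups, truth)``: a features × samples
    DataFrame, per-feature lengths (bp), per-sample time-point labels, and
    the ground-truth archetype index per feature (-1 for null features).
    """
    spec = spec or OmicsSimSpec()
    rng = np.random.default_rng(spec.seed)
    n_t, n_r = len(spec.timepoints), spec.replicates
    n_null = int(round(spec.fraction_null * spec.n_features))
    n_signal = spec.n_features - n_null

    truth = np.full(spec.n_features, -1, dtype=int)
    if n_signal:
        truth[:n_signal] = np.arange(n_signal) % spec.k_clusters
    rng.shuffle(truth)

    # per-feature baseline spans ~2 orders of magnitude
    baseline = spec.base_mean * rng.lognormal(0.0, 0.8, size=spec.n_features)
    profiles = ARCHETYPES[: spec.k_clusters] - ARCHETYPES[
        : spec.k_clusters
    ].mean(axis=1, keepdims=True)

    means = np.empty((spec.n_features, n_t))
    for i, cl in enumerate(truth):
        shape = profiles[cl] if cl >= 0 else np.zeros(n_t)
        means[i] = baseline[i] * 2.0 ** (spec.amplitude * shape)

    r = 1.0 / spec.dispersion
    cols, data = [], []
    for j, tp in enumerate(spec.timepoints):
        for rep in range(1, n_r + 1):
            m = means[:, j]
            p = r / (r + m)
            data.append(rng.negative_binomial(r, p))
            cols.append(f"t{tp}_r{rep}")
    features = [f"gene_{i:05d}" for i in range(spec.n_features)]
    counts = pd.DataFrame(
        np.column_stack(data), index=features, columns=cols
    )
    lengths = pd.Series(
        np.round(rng.lognormal(np.log(1000.0), 0.45, spec.n_features)).astype(int),
        index=features, name="length",
    ).clip(lower=100)
    groups = pd.Series(
        [int(c.split("_")[0][1:]) for c in cols], index=cols, name="timepoint"
    )
    truth = pd.Series(truth, index=features, name="archetype")
    return counts, lengths, groups, truth


# ---------------------------------------------------------------------------
# Ranked lists with planted enrichment
# ---------------------------------------------------------------------------

def make_ranked_group(
    n_total: int, group_size: int, enrichment_top: int, seed: int = 0
) -> RankedGroup:
    """A ranked list whose group has ``enrichment_top`` members planted
    uniformly in the top decile and the remainder uniformly below it."""
    if not 0 <= enrichment_top <= group_size <= n_total:
        raise ValueError(
            "need 0 <= enrichment_top <= group_size <= n_total"
        )
    decile = max(n_total // 10, 1)
    if enrichment_top > decile:
        raise ValueError("enrichment_top exceeds the top decile size")
    if group_size - enrichment_top > n_total - decile:
        raise ValueError("too many non-enriched members for the tail")
    rng = np.random.default_rng(seed)
    membership = np.zeros(n_total, dtype=bool)
    top = rng.choice(decile, size=enrichment_top, replace=False)
    rest = rng.choice(
        np.arange(decile, n_total), size=group_size - enrichment_top,
        replace=False,
    )
    membership[top] = True
    membership[rest] = True
    return RankedGroup(membership=membership)
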