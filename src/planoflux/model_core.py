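"""Stoichiometric model container, FBA, and orthology-based pruning.

The model container is deliberately small: metabolites, reactions with
signed stoichiometry and bounds, boolean gene rules, and a single objective
reaction.  Flux balance analysis (FBA) maximizes the objective flux subject
to steady state ``S v = 0`` and the flux bounds; a parsimonious second stage
(fix the optimum, minimize the total absolute flux) makes the reported flux
vector reproducible in the presence of alternate optima, which matters when
exchange fluxes drive a dynamic simulation.

Sign convention: negative exchange flux is uptake; exchange reaction ids
start with ``EX_`` and touch exactly one extracellular metabolite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "Metabolite",
    "Reaction",
    "StoichiometricModel",
    "FluxSolution",
    "ModelValidationError",
    "GeneRuleError",
    "parse_gene_rule",
    "eval_gene_rule",
    "gene_rule_genes",
    "load_model",
    "save_model",
    "solve_fba",
    "prune_by_orthology",
    "phosphorus_imbalance",
]

#: feasibility tolerance handed to the LP solver
LP_FEASIBILITY_TOL = 1e-9
#: tolerance for checking S v = 0 on a reported solution
MASS_BALANCE_TOL = 1e-6

CYTOSOL = "c"
EXTRACELLULAR = "e"


class ModelValidationError(ValueError):
    """A model violates a structural invariant."""


class GeneRuleError(ValueError):
    """A gene rule string cannot be parsed."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = CYTOSOL
    formula: str | None = None
    phosphorus_count: int | None = None

    def __post_init__(self) -> None:
        if self.phosphorus_count is not None and self.phosphorus_count < 0:
            raise ModelValidationError(
                f"metabolite {self.id}: phosphorus_count must be >= 0"
            )


@dataclass
class Reaction:
    """A reaction with signed stoichiometry (negative = consumed).

    Bounds are mmol/gDW/h, except the biomass pseudo-reaction whose flux is
    the specific growth rate in 1/h.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gene_rule: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id}: lower_bound > upper_bound"
            )

    @property
    def is_exchange(self) -> bool:
        return self.id.startswith("EX_")

    @property
    def is_boundary(self) -> bool:
        """Exchange, sink or demand: a single-metabolite boundary reaction."""
        return len(self.stoichiometry) == 1

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


@dataclass
class StoichiometricModel:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    objective_id: str
    annotations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups ---------------------------------------------------------
    @property
    def metabolite_ids(self) -> set[str]:
        return {m.id for m in self.metabolites}

    def metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(met_id)

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    def has_reaction(self, rxn_id: str) -> bool:
        return any(r.id == rxn_id for r in self.reactions)

    def has_metabolite(self, met_id: str) -> bool:
        return any(m.id == met_id for m in self.metabolites)

    def genes(self) -> set[str]:
        out: set[str] = set()
        for r in self.reactions:
            out |= gene_rule_genes(r.gene_rule)
        return out

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(met_ids) != len(set(met_ids)):
            raise ModelValidationError("duplicate metabolite ids")
        rxn_ids = [r.id for r in self.reactions]
        if len(rxn_ids) != len(set(rxn_ids)):
            raise ModelValidationError("duplicate reaction ids")
        known = set(met_ids)
        for r in self.reactions:
            missing = set(r.stoichiometry) - known
            if missing:
                raise ModelValidationError(
                    f"reaction {r.id} references undeclared metabolites: "
                    f"{sorted(missing)}"
                )
            if r.is_exchange:
                ex_mets = [
                    m for m in r.stoichiometry
                    if self.metabolite(m).compartment == EXTRACELLULAR
                ]
                if len(r.stoichiometry) != 1 or len(ex_mets) != 1:
                    raise ModelValidationError(
                        f"exchange {r.id} must touch exactly one "
                        "extracellular metabolite"
                    )
        if self.objective_id not in set(rxn_ids):
            raise ModelValidationError(
                f"objective reaction {self.objective_id!r} not in model"
            )

    def copy(self) -> "StoichiometricModel":
        return StoichiometricModel(
            metabolites=[replace(m) for m in self.metabolites],
            reactions=[r.copy() for r in self.reactions],
            objective_id=self.objective_id,
            annotations=dict(self.annotations),
        )


@dataclass
class FluxSolution:
    status: str  # "optimal" | "infeasible"
    objective_value: float
    fluxes: dict[str, float]

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


# ---------------------------------------------------------------------------
# Gene rules: infix boolean expressions over gene ids, "and"/"or",
# case-insensitive, parentheses allowed.  Absent genes evaluate false.
# ---------------------------------------------------------------------------

def _tokenize_rule(rule: str) -> list[str]:
    out: list[str] = []
    tok = ""
    for ch in rule:
        if ch in "()":
            if tok:
                out.append(tok)
                tok = ""
            out.append(ch)
        elif ch.isspace():
            if tok:
                out.append(tok)
                tok = ""
        else:
            tok += ch
    if tok:
        out.append(tok)
    return out


def parse_gene_rule(rule: str):
    """Parse a gene rule into a nested ('and'|'or', [children]) / gene tree.

    Returns ``None`` for an empty rule.  ``or`` binds looser than ``and``.
    """
    tokens = _tokenize_rule(rule)
    if not tokens:
        return None
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def parse_or():
        nonlocal pos
        terms = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            pos += 1
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else ("or", terms)

    def parse_and():
        nonlocal pos
        terms = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            pos += 1
            terms.append(parse_atom())
        return terms[0] if len(terms) == 1 else ("and", terms)

    def parse_atom():
        nonlocal pos
        tok = peek()
        if tok is None:
            raise GeneRuleError(f"unexpected end of rule: {rule!r}")
        if tok == "(":
            pos += 1
            node = parse_or()
            if peek() != ")":
                raise GeneRuleError(f"unbalanced parentheses in {rule!r}")
            pos += 1
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GeneRuleError(f"unexpected token {tok!r} in {rule!r}")
        pos += 1
        return tok

    tree = parse_or()
    if pos != len(tokens):
        raise GeneRuleError(f"trailing tokens in {rule!r}")
    return tree


def _eval_tree(node, present: set[str]) -> bool:
    if isinstance(node, str):
        return node in present
    op, children = node
    if op == "and":
        return all(_eval_tree(c, present) for c in children)
    return any(_eval_tree(c, present) for c in children)


def eval_gene_rule(rule: str, present_genes: set[str]) -> bool:
    """True iff the rule is satisfied when genes outside the set are absent.

    An empty rule is vacuously true (spontaneous / non-gene-associated
    reactions stay).
    """
    tree = parse_gene_rule(rule)
    if tree is None:
        return True
    return _eval_tree(tree, present_genes)


def gene_rule_genes(rule: str) -> set[str]:
    tree = parse_gene_rule(rule)
    out: set[str] = set()

    def walk(node):
        if node is None:
            return
        if isinstance(node, str):
            out.add(node)
            return
        for c in node[1]:
            walk(c)

    walk(tree)
    return out


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------

def _build_matrices(model: StoichiometricModel):
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    n_m, n_r = len(model.metabolites), len(model.reactions)
    S = np.zeros((n_m, n_r))
    lb = np.empty(n_r)
    ub = np.empty(n_r)
    for j, r in enumerate(model.reactions):
        lb[j], ub[j] = r.lower_bound, r.upper_bound
        for met, coeff in r.stoichiometry.items():
            S[met_index[met], j] = coeff
    return S, lb, ub


def solve_fba(
    model: StoichiometricModel, parsimonious: bool = True
) -> FluxSolution:
    """Maximize the objective flux; optionally break degeneracy parsimoniously.

    The second stage fixes the optimal objective value and minimizes the sum
    of absolute fluxes, making exchange fluxes unique in practice.  Infeasible
    problems return ``status="infeasible"`` with objective 0 and no fluxes.
    """
    S, lb, ub = _build_matrices(model)
    n_r = S.shape[1]
    obj_idx = [r.id for r in model.reactions].index(model.objective_id)
    c = np.zeros(n_r)
    c[obj_idx] = -1.0  # linprog minimizes

    options = {"primal_feasibility_tolerance": LP_FEASIBILITY_TOL}
    res = linprog(
        c, A_eq=S, b_eq=np.zeros(S.shape[0]),
        bounds=np.column_stack([lb, ub]), method="highs", options=options,
    )
    if not res.success:
        return FluxSolution("infeasible", 0.0, {})
    mu = float(res.x[obj_idx])
    v = res.x

    if parsimonious:
        # min sum(v+ + v-) with v = v+ - v-, S v = 0, v_obj = mu, lb<=v<=ub
        lb_pos = np.maximum(lb, 0.0)
        ub_pos = np.maximum(ub, 0.0)
        lb_neg = np.maximum(-ub, 0.0)
        ub_neg = np.maximum(-lb, 0.0)
        A_eq = np.hstack([S, -S])
        b_eq = np.zeros(S.shape[0])
        row = np.zeros(2 * n_r)
        row[obj_idx] = 1.0
        row[n_r + obj_idx] = -1.0
        A_eq = np.vstack([A_eq, row])
        b_eq = np.append(b_eq, mu)
        bounds2 = np.column_stack(
            [np.concatenate([lb_pos, lb_neg]), np.concatenate([ub_pos, ub_neg])]
        )
        res2 = linprog(
            np.ones(2 * n_r), A_eq=A_eq, b_eq=b_eq, bounds=bounds2,
            method="highs", options=options,
        )
        if res2.success:
            v = res2.x[:n_r] - res2.x[n_r:]

    imbalance = np.abs(S @ v)
    if imbalance.max(initial=0.0) > MASS_BALANCE_TOL:
        raise RuntimeError(
            f"LP returned a mass-imbalanced solution (max |S v| = "
            f"{imbalance.max():.3g})"
        )
    fluxes = {r.id: float(v[j]) for j, r in enumerate(model.reactions)}
    return FluxSolution("optimal", mu, fluxes)


# ---------------------------------------------------------------------------
# Orthology pruning
# ---------------------------------------------------------------------------

def prune_by_orthology(
    model: StoichiometricModel, retained_genes: set[str]
) -> StoichiometricModel:
    """Remove reactions whose gene rule fails with only ``retained_genes``.

    Reactions with an empty rule are kept; metabolites left orphaned are
    dropped.  Idempotent and monotone in the retained set.
    """
    kept = [
        r.copy() for r in model.reactions
        if eval_gene_rule(r.gene_rule, retained_genes)
    ]
    if model.objective_id not in {r.id for r in kept}:
        raise ModelValidationError(
            "pruning removed the objective reaction "
            f"{model.objective_id!r}"
        )
    used = {m for r in kept for m in r.stoichiometry}
    mets = [replace(m) for m in model.metabolites if m.id in used]
    return StoichiometricModel(
        metabolites=mets, reactions=kept,
        objective_id=model.objective_id, annotations=dict(model.annotations),
    )


# ---------------------------------------------------------------------------
# Phosphorus audit
# ---------------------------------------------------------------------------

def phosphorus_imbalance(
    model: StoichiometricModel, reaction: Reaction
) -> float | None:
    """Net P atoms produced by the reaction, or None if any P count is missing.

    Boundary reactions (single metabolite) and biomass pseudo-reactions are
    inherently unbalanced and should be exempted by the caller.
    """
    total = 0.0
    for met_id, coeff in reaction.stoichiometry.items():
        p = model.metabolite(met_id).phosphorus_count
        if p is None:
            return None
        total += coeff * p
    return total


# ---------------------------------------------------------------------------
# I/O: a JSON dialect mirroring the dataclasses, and SBML L3+fbc via cobrapy
# ---------------------------------------------------------------------------

def _model_to_dict(model: StoichiometricModel) -> dict:
    return {
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": m.formula,
                "phosphorus_count": m.phosphorus_count,
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": dict(sorted(r.stoichiometry.items())),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_rule": r.gene_rule,
            }
            for r in model.reactions
        ],
        "objective_id": model.objective_id,
        "annotations": dict(sorted(model.annotations.items())),
    }


def _model_from_dict(data: dict) -> StoichiometricModel:
    try:
        mets = [
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment", CYTOSOL),
                formula=m.get("formula"),
                phosphorus_count=m.get("phosphorus_count"),
            )
            for m in data["metabolites"]
        ]
        rxns = [
            Reaction(
                id=r["id"],
                name=r.get("name", ""),
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                lower_bound=float(r["lower_bound"]),
                upper_bound=float(r["upper_bound"]),
                gene_rule=r.get("gene_rule", ""),
            )
            for r in data["reactions"]
        ]
        objective = data["objective_id"]
    except KeyError as exc:
        raise ModelValidationError(f"missing required field: {exc}") from exc
    return StoichiometricModel(
        metabolites=mets, reactions=rxns, objective_id=objective,
        annotations=dict(data.get("annotations", {})),
    )


def to_cobra(model: StoichiometricModel):
    """Convert to a cobrapy model (for SBML I/O and as a test oracle)."""
    import cobra

    cm = cobra.Model(model.annotations.get("id", "model"))
    cmets = {}
    for m in model.metabolites:
        cmet = cobra.Metabolite(
            m.id, name=m.name, compartment=m.compartment, formula=m.formula
        )
        if m.phosphorus_count is not None:
            cmet.notes["phosphorus_count"] = str(m.phosphorus_count)
        cmets[m.id] = cmet
    cm.add_metabolites(list(cmets.values()))
    crxns = []
    for r in model.reactions:
        cr = cobra.Reaction(
            r.id, name=r.name,
            lower_bound=r.lower_bound, upper_bound=r.upper_bound,
        )
        crxns.append(cr)
    cm.add_reactions(crxns)
    for r, cr in zip(model.reactions, crxns):
        cr.add_metabolites({cmets[k]: v for k, v in r.stoichiometry.items()})
        if r.gene_rule:
            cr.gene_reaction_rule = r.gene_rule
    cm.objective = model.objective_id
    return cm


def from_cobra(cm) -> StoichiometricModel:
    mets = []
    for cmet in cm.metabolites:
        p = cmet.notes.get("phosphorus_count")
        mets.append(
            Metabolite(
                id=cmet.id, name=cmet.name or "",
                compartment=cmet.compartment or CYTOSOL,
                formula=cmet.formula or None,
                phosphorus_count=int(p) if p is not None else None,
            )
        )
    rxns = [
        Reaction(
            id=cr.id, name=cr.name or "",
            stoichiometry={m.id: float(v) for m, v in cr.metabolites.items()},
            lower_bound=float(cr.lower_bound),
            upper_bound=float(cr.upper_bound),
            gene_rule=cr.gene_reaction_rule or "",
        )
        for cr in cm.reactions
    ]
    objective = None
    for cr in cm.reactions:
        if cr.objective_coefficient:
            objective = cr.id
            break
    if objective is None:
        raise ModelValidationError("SBML model declares no objective reaction")
    return StoichiometricModel(
        metabolites=mets, reactions=rxns, objective_id=objective
    )


def save_model(
    model: StoichiometricModel, path, format: str = "json"
) -> None:
    path = str(path)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(_model_to_dict(model), fh, indent=1, sort_keys=True)
            fh.write("\n")
    elif format == "sbml":
        import cobra.io

        cobra.io.write_sbml_model(to_cobra(model), path)
    else:
        raise ValueError(f"unknown format {format!r}")


def load_model(path, format: str = "json") -> StoichiometricModel:
    """Load a model from JSON (this package's dialect) or SBML L3+fbc."""
    path = str(path)
    if format == "json":
        with open(path) as fh:
            try:
                data = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ModelValidationError(
                    f"cannot parse {path} as JSON: {exc}"
                ) from exc
        return _model_from_dict(data)
    if format == "sbml":
        import cobra.io

        return from_cobra(cobra.io.read_sbml_model(path))
    raise ValueError(f"unknown format {format!r}")
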