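"""Stoichiometric model data structures and the linear-programming contract.

All fluxes throughout the package are expressed in mmol/day per person --
the natural unit for dietary intake constraints and for a fecal-emptying
community biomass -- rather than the per-gram-dry-weight-per-hour unit
common for single-organism models.

The system-boundary convention is export-positive: an exchange reaction is
written ``met -> (nothing)``; positive flux carries the metabolite out of
the system, negative flux imports it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linprog

#: Default "open" flux bound, mmol/day.  Effectively unconstrained while
#: keeping every LP bounded.
DEFAULT_BOUND = 1e6

#: Absolute feasibility/optimality tolerance for LP solutions.
SOLVER_TOL = 1e-6

REACTION_KINDS = ("internal", "transport", "exchange", "biomass", "community_biomass")


class ModelError(Exception):
    """Structural problem with a model (parse or validation failure)."""


class InfeasibleError(Exception):
    """Raised when an operation requires an optimal solution but the LP
    is infeasible or unbounded."""

    def __init__(self, status: str, message: str = ""):
        self.status = status
        super().__init__(message or f"LP terminated with status '{status}'")


@dataclass
class Metabolite:
    """A chemical species located in one compartment.

    molecular_weight is in g/mol and is used only by the diet builder's
    mass-to-mole conversion; it plays no role in flux balance itself.
    """

    id: str
    name: str = ""
    compartment: str = "c"
    molecular_weight: float | None = None


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    kind: str = "internal"

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound


@dataclass
class Taxonomy:
    phylum: str = ""
    family: str = ""
    genus: str = ""
    species: str = ""

    def rank(self, rank: str) -> str:
        return getattr(self, rank)

    def as_dict(self) -> dict[str, str]:
        return {
            "phylum": self.phylum,
            "family": self.family,
            "genus": self.genus,
            "species": self.species,
        }


@dataclass
class FluxRange:
    """Closed interval of attainable flux (mmol/day), as returned by FVA."""

    minimum: float
    maximum: float

    def __iter__(self):
        yield self.minimum
        yield self.maximum


@dataclass
class LinearConstraint:
    """One inequality row  sum_i coefficients[r_i] * v_i <= bound.

    Used for the biomass-coupling rows of community models and for ad-hoc
    extra constraints passed to :func:`solve_lp`.
    """

    coefficients: dict[str, float]
    bound: float
    name: str = ""


@dataclass
class SolverSolution:
    status: str  # optimal | infeasible | unbounded
    objective_value: float | None
    fluxes: dict[str, float]

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


@dataclass
class TaxonModel:
    """One organism's stoichiometric metabolic model.

    ``model_id`` plays the role of a reconstruction-resource identifier
    (e.g. an AGORA model id); reactions and metabolites are stored in
    insertion-ordered dicts keyed by id.
    """

    model_id: str
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    biomass_reaction_id: str = ""
    taxonomy: Taxonomy | None = None

    def add_metabolite(self, met: Metabolite) -> None:
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        self.reactions[rxn.id] = rxn

    @property
    def compartments(self) -> set[str]:
        return {m.compartment for m in self.metabolites.values()}

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.kind == "exchange"]

    def biomass_metabolite_id(self) -> str:
        """The single metabolite produced by the biomass reaction."""
        rxn = self.reactions[self.biomass_reaction_id]
        produced = [m for m, c in rxn.stoichiometry.items() if c > 0]
        if len(produced) != 1:
            raise ModelError(
                f"biomass reaction {rxn.id!r} must produce exactly one "
                f"biomass metabolite, found {produced}"
            )
        return produced[0]

    def copy(self) -> "TaxonModel":
        m = TaxonModel(
            model_id=self.model_id,
            biomass_reaction_id=self.biomass_reaction_id,
            taxonomy=replace(self.taxonomy) if self.taxonomy else None,
        )
        for met in self.metabolites.values():
            m.add_metabolite(replace(met))
        for rxn in self.reactions.values():
            m.add_reaction(
                Reaction(
                    id=rxn.id,
                    stoichiometry=dict(rxn.stoichiometry),
                    lower_bound=rxn.lower_bound,
                    upper_bound=rxn.upper_bound,
                    kind=rxn.kind,
                )
            )
        return m


def validate_model(model: TaxonModel) -> list[str]:
    """Check every structural invariant; return a list of violations.

    An empty list means the model is valid.  This is a reporting
    operation and never raises.
    """
    violations: list[str] = []
    seen_met: set[str] = set()
    for mid, met in model.metabolites.items():
        if not mid:
            violations.append("metabolite with empty id")
        if mid != met.id:
            violations.append(f"metabolite key {mid!r} != id {met.id!r}")
        if mid in seen_met:
            violations.append(f"duplicate metabolite id {mid!r}")
        seen_met.add(mid)

    seen_rxn: set[str] = set()
    for rid, rxn in model.reactions.items():
        if rid != rxn.id:
            violations.append(f"reaction key {rid!r} != id {rxn.id!r}")
        if rid in seen_rxn:
            violations.append(f"duplicate reaction id {rid!r}")
        seen_rxn.add(rid)
        if rxn.kind not in REACTION_KINDS:
            violations.append(f"reaction {rid!r}: unknown kind {rxn.kind!r}")
        if not rxn.lower_bound <= rxn.upper_bound:
            violations.append(
                f"reaction {rid!r}: lower_bound {rxn.lower_bound} > "
                f"upper_bound {rxn.upper_bound}"
            )
        if not rxn.stoichiometry:
            violations.append(f"reaction {rid!r}: empty stoichiometry")
        for mid in rxn.stoichiometry:
            if mid not in model.metabolites:
                violations.append(
                    f"reaction {rid!r} references undeclared metabolite {mid!r}"
                )
        if rxn.kind == "exchange" and len(rxn.stoichiometry) != 1:
            violations.append(
                f"exchange reaction {rid!r} must touch exactly one metabolite"
            )
        if rxn.kind == "biomass":
            produced = [m for m, c in rxn.stoichiometry.items() if c > 0]
            if len(produced) != 1:
                violations.append(
                    f"biomass reaction {rid!r} must produce exactly one "
                    "biomass metabolite"
                )

    if not model.biomass_reaction_id:
        violations.append("no biomass_reaction_id declared")
    elif model.biomass_reaction_id not in model.reactions:
        violations.append(
            f"biomass_reaction_id {model.biomass_reaction_id!r} not among reactions"
        )
    elif model.reactions[model.biomass_reaction_id].kind not in (
        "biomass",
        "community_biomass",
    ):
        violations.append(
            f"reaction {model.biomass_reaction_id!r} does not have kind=biomass"
        )
    return violations


def require_valid(model: TaxonModel) -> None:
    violations = validate_model(model)
    if violations:
        raise ModelError(
            f"model {model.model_id!r} is invalid:\n  " + "\n  ".join(violations)
        )


# ---------------------------------------------------------------------------
# LP assembly and solving
# ---------------------------------------------------------------------------


@dataclass
class LPArrays:
    """Matrix view of a model: S v = 0, A_ub v <= b_ub, lb <= v <= ub."""

    reaction_ids: list[str]
    metabolite_ids: list[str]
    S: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    A_ub: np.ndarray | None
    b_ub: np.ndarray | None
    index: dict[str, int]


def build_lp_arrays(
    model: TaxonModel, extra_constraints: list[LinearConstraint] | None = None
) -> LPArrays:
    """Assemble dense LP arrays from a model plus optional inequality rows.

    Community models carry their coupling rows in ``model.coupling``; these
    are appended automatically.
    """
    reaction_ids = list(model.reactions)
    metabolite_ids = list(model.metabolites)
    ridx = {r: i for i, r in enumerate(reaction_ids)}
    midx = {m: i for i, m in enumerate(metabolite_ids)}
    n, m = len(reaction_ids), len(metabolite_ids)
    S = np.zeros((m, n))
    lb = np.empty(n)
    ub = np.empty(n)
    for j, rid in enumerate(reaction_ids):
        rxn = model.reactions[rid]
        lb[j] = rxn.lower_bound
        ub[j] = rxn.upper_bound
        for mid, coef in rxn.stoichiometry.items():
            S[midx[mid], j] = coef

    rows: list[LinearConstraint] = []
    rows.extend(getattr(model, "coupling", []) or [])
    rows.extend(extra_constraints or [])
    if rows:
        A = np.zeros((len(rows), n))
        b = np.empty(len(rows))
        for i, con in enumerate(rows):
            b[i] = con.bound
            for rid, coef in con.coefficients.items():
                A[i, ridx[rid]] = coef
        A_ub, b_ub = A, b
    else:
        A_ub = b_ub = None
    return LPArrays(reaction_ids, metabolite_ids, S, lb, ub, A_ub, b_ub, ridx)


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def _solve_arrays(arrays: LPArrays, c: np.ndarray) -> tuple[str, float | None, np.ndarray | None]:
    res = linprog(
        c,
        A_ub=arrays.A_ub,
        b_ub=arrays.b_ub,
        A_eq=arrays.S,
        b_eq=np.zeros(arrays.S.shape[0]),
        bounds=np.column_stack([arrays.lb, arrays.ub]),
        method="highs",
    )
    status = _STATUS.get(res.status, "numerical")
    if status == "optimal":
        return status, float(res.fun), res.x
    return status, None, None


def solve_lp(
    model: TaxonModel,
    objective: str,
    sense: str = "max",
    extra_constraints: list[LinearConstraint] | None = None,
) -> SolverSolution:
    """Flux balance analysis: optimize one reaction's flux.

    Returns a :class:`SolverSolution`; infeasible and unbounded statuses
    are returned as-is, never silently clamped.  At an optimum the flux
    vector satisfies steady state and all bounds within ``SOLVER_TOL``.
    """
    if objective not in model.reactions:
        raise KeyError(f"objective reaction {objective!r} not in model")
    if sense not in ("max", "min"):
        raise ValueError("sense must be 'max' or 'min'")
    arrays = build_lp_arrays(model, extra_constraints)
    c = np.zeros(len(arrays.reaction_ids))
    c[arrays.index[objective]] = -1.0 if sense == "max" else 1.0
    status, fun, x = _solve_arrays(arrays, c)
    if status != "optimal":
        return SolverSolution(status=status, objective_value=None, fluxes={})
    obj = -fun if sense == "max" else fun
    fluxes = dict(zip(arrays.reaction_ids, (float(v) for v in x)))
    return SolverSolution(status="optimal", objective_value=obj, fluxes=fluxes)


def steady_state_residual(model: TaxonModel, fluxes: dict[str, float]) -> float:
    """Largest absolute metabolite imbalance ||S v||_inf for a flux vector."""
    arrays = build_lp_arrays(model)
    v = np.array([fluxes.get(r, 0.0) for r in arrays.reaction_ids])
    if arrays.S.size == 0:
        return 0.0
    return float(np.max(np.abs(arrays.S @ v)))


def fba_max(model: TaxonModel, objective: str | None = None) -> float:
    """Convenience: maximal flux through ``objective`` (default biomass).

    Raises :class:`InfeasibleError` when no optimum exists.
    """
    objective = objective or model.biomass_reaction_id
    sol = solve_lp(model, objective, "max")
    if not sol.ok:
        raise InfeasibleError(sol.status)
    assert sol.objective_value is not None
    return sol.objective_value
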