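"""Join per-taxon models into one community-scale model.

The community scaffold has three shared flux boundaries around a common
gut *lumen* compartment (label ``u``):

* one diet exchange per lumen metabolite (``EX_x[d]``), import-only —
  its lower bound carries the dietary uptake flux;
* one fecal exchange per lumen metabolite (``EX_x[fe]``), export-only;
* per taxon and extracellular metabolite, a reversible lumen-transfer
  reaction (``IEX__<tag>__x``), positive toward the lumen (secretion).

Member models are namespaced with a taxon tag; their own exchange
reactions are removed (the lumen scaffold is the only system boundary).
A community biomass reaction consumes each member's biomass metabolite
with its relative abundance as stoichiometric coefficient and produces
one unit of community biomass, whose exchange is bounded to
[0.4, 1] mmol/day by default — fecal emptying between every three days
and once per day.

Coupling constraints tie each member reaction's flux magnitude to that
member's biomass flux, |v_r| <= c * v_bio + u, preventing growth-free
metabolic activity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from .core import (
    DEFAULT_BOUND,
    LinearConstraint,
    Metabolite,
    ModelError,
    Reaction,
    TaxonModel,
    require_valid,
)
from .diet import DietSpec

TAG_SEP = "__"
LUMEN = "u"

#: Default community biomass exchange bounds, mmol/day.
DEFAULT_BIOMASS_BOUNDS = (0.4, 1.0)

#: Default trace import bound for gap-filled micronutrients, mmol/day.
DEFAULT_TRACE_BOUND = 0.1


@dataclass
class CouplingConfig:
    """Biomass-coupling parameters: |v_r| <= c * v_biomass + u."""

    c: float = 400.0  # dimensionless coupling factor
    u: float = 0.0  # slack, mmol/day

    def __post_init__(self):
        if self.c <= 0:
            raise ValueError("coupling factor c must be > 0")
        if self.u < 0:
            raise ValueError("coupling slack u must be >= 0")


def _base_name(met: Metabolite) -> str:
    """Strip a trailing [compartment] suffix from a metabolite id."""
    suffix = f"[{met.compartment}]"
    return met.id[: -len(suffix)] if met.id.endswith(suffix) else met.id


@dataclass
class CommunityModel(TaxonModel):
    """A merged multi-taxon model with lumen/diet/fecal scaffold."""

    members: dict[str, str] = field(default_factory=dict)  # tag -> model_id
    abundances: dict[str, float] = field(default_factory=dict)  # tag -> fraction
    coupling: list[LinearConstraint] = field(default_factory=list)
    coupling_config: CouplingConfig | None = None
    member_biomass: dict[str, str] = field(default_factory=dict)  # tag -> rxn id
    member_reactions: dict[str, list[str]] = field(default_factory=dict)
    lumen_bases: list[str] = field(default_factory=list)
    diet_name: str | None = None
    unresolved_diet: list[str] = field(default_factory=list)

    def diet_exchange_id(self, base: str) -> str:
        return f"EX_{base}[d]"

    def fecal_exchange_id(self, base: str) -> str:
        return f"EX_{base}[fe]"

    def transfer_id(self, tag: str, base: str) -> str:
        return f"IEX{TAG_SEP}{tag}{TAG_SEP}{base}"

    def copy(self) -> "CommunityModel":
        m = CommunityModel(
            model_id=self.model_id,
            biomass_reaction_id=self.biomass_reaction_id,
            members=dict(self.members),
            abundances=dict(self.abundances),
            coupling=[
                LinearConstraint(dict(c.coefficients), c.bound, c.name) for c in self.coupling
            ],
            coupling_config=replace(self.coupling_config) if self.coupling_config else None,
            member_biomass=dict(self.member_biomass),
            member_reactions={k: list(v) for k, v in self.member_reactions.items()},
            lumen_bases=list(self.lumen_bases),
            diet_name=self.diet_name,
            unresolved_diet=list(self.unresolved_diet),
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


def tag_taxon_model(model: TaxonModel, tag: str) -> TaxonModel:
    """Namespace every metabolite and reaction id with ``tag``.

    Stoichiometry, bounds and kinds are untouched; the lumen-transfer
    reactions for extracellular metabolites are created later, at
    community build time.
    """
    if not tag:
        raise ModelError("taxon tag must be nonempty")
    tagged = TaxonModel(
        model_id=model.model_id,
        biomass_reaction_id=f"{tag}{TAG_SEP}{model.biomass_reaction_id}",
        taxonomy=model.taxonomy,
    )
    for met in model.metabolites.values():
        tagged.add_metabolite(
            Metabolite(
                id=f"{tag}{TAG_SEP}{met.id}",
                name=met.name,
                compartment=met.compartment,
                molecular_weight=met.molecular_weight,
            )
        )
    for rxn in model.reactions.values():
        tagged.add_reaction(
            Reaction(
                id=f"{tag}{TAG_SEP}{rxn.id}",
                stoichiometry={
                    f"{tag}{TAG_SEP}{mid}": coef for mid, coef in rxn.stoichiometry.items()
                },
                lower_bound=rxn.lower_bound,
                upper_bound=rxn.upper_bound,
                kind=rxn.kind,
            )
        )
    return tagged


def build_community(
    models: list[TaxonModel],
    abundances: dict[str, float],
    coupling: CouplingConfig | None = None,
    biomass_bounds: tuple[float, float] = DEFAULT_BIOMASS_BOUNDS,
    couple: bool = True,
    model_id: str = "community",
) -> CommunityModel:
    """Merge taxon models into a CommunityModel.

    ``abundances`` maps each model's id to its relative abundance; they
    must sum to 1 (tolerance 1e-9) and be strictly positive.  Tags equal
    the model ids.  Coupling rows are added unless ``couple=False``.
    """
    if not models:
        raise ModelError("cannot build a community from zero members")
    ids = [m.model_id for m in models]
    if len(set(ids)) != len(ids):
        raise ModelError(f"duplicate taxon tags in community: {ids}")
    if set(abundances) != set(ids):
        raise ModelError(
            f"abundance keys {sorted(abundances)} do not match model ids {sorted(ids)}"
        )
    if any(a <= 0 for a in abundances.values()):
        raise ModelError("all abundances must be strictly positive")
    total = sum(abundances.values())
    if abs(total - 1.0) > 1e-9:
        raise ModelError(f"abundances must sum to 1 (got {total!r})")

    coupling = coupling or CouplingConfig()
    cm = CommunityModel(model_id=model_id, coupling_config=coupling)
    biomass_stoich: dict[str, float] = {}
    lumen_bases: list[str] = []

    for model in models:
        require_valid(model)
        tag = model.model_id
        cm.members[tag] = model.model_id
        cm.abundances[tag] = abundances[tag]
        biomass_met = model.biomass_metabolite_id()
        tagged = tag_taxon_model(model, tag)
        member_rxns: list[str] = []
        for met in tagged.metabolites.values():
            cm.add_metabolite(met)
        for rxn in tagged.reactions.values():
            if rxn.kind == "exchange":
                continue  # the lumen scaffold is the only system boundary
            cm.add_reaction(rxn)
            member_rxns.append(rxn.id)
        # lumen transfers for extracellular metabolites
        for met in model.metabolites.values():
            if met.compartment != "e":
                continue
            base = _base_name(met)
            lumen_id = f"{base}[{LUMEN}]"
            if lumen_id not in cm.metabolites:
                cm.add_metabolite(
                    Metabolite(id=lumen_id, name=met.name or base, compartment=LUMEN)
                )
                lumen_bases.append(base)
            iex = Reaction(
                id=cm.transfer_id(tag, base),
                stoichiometry={f"{tag}{TAG_SEP}{met.id}": -1.0, lumen_id: 1.0},
                lower_bound=-DEFAULT_BOUND,
                upper_bound=DEFAULT_BOUND,
                kind="transport",
            )
            cm.add_reaction(iex)
            member_rxns.append(iex.id)
        cm.member_biomass[tag] = tagged.biomass_reaction_id
        cm.member_reactions[tag] = member_rxns
        biomass_stoich[f"{tag}{TAG_SEP}{biomass_met}"] = -abundances[tag]

    # diet + fecal exchanges for every lumen metabolite
    for base in lumen_bases:
        lumen_id = f"{base}[{LUMEN}]"
        cm.add_reaction(
            Reaction(
                id=cm.diet_exchange_id(base),
                stoichiometry={lumen_id: -1.0},
                lower_bound=0.0,  # closed to import until a diet is applied
                upper_bound=0.0,  # diet exchanges never export
                kind="exchange",
            )
        )
        cm.add_reaction(
            Reaction(
                id=cm.fecal_exchange_id(base),
                stoichiometry={lumen_id: -1.0},
                lower_bound=0.0,  # fecal exchanges are export-only
                upper_bound=DEFAULT_BOUND,
                kind="exchange",
            )
        )
    cm.lumen_bases = lumen_bases

    # community biomass: abundance-weighted consumption of member biomass
    cbio_met = f"community_biomass[{LUMEN}]"
    cm.add_metabolite(Metabolite(id=cbio_met, name="community biomass", compartment=LUMEN))
    biomass_stoich[cbio_met] = 1.0
    cm.add_reaction(
        Reaction(
            id="community_biomass",
            stoichiometry=biomass_stoich,
            lower_bound=0.0,
            upper_bound=DEFAULT_BOUND,
            kind="community_biomass",
        )
    )
    cm.add_reaction(
        Reaction(
            id="EX_community_biomass[fe]",
            stoichiometry={cbio_met: -1.0},
            lower_bound=biomass_bounds[0],
            upper_bound=biomass_bounds[1],
            kind="exchange",
        )
    )
    cm.biomass_reaction_id = "community_biomass"

    if couple:
        apply_coupling(cm, coupling)
    return cm


def apply_coupling(model: CommunityModel, coupling: CouplingConfig | None = None) -> CommunityModel:
    """(Re)build the biomass-coupling rows, in place.

    For every non-biomass reaction r of taxon k (including its lumen
    transfers):  v_r - c*v_bio_k <= u  and  -v_r - c*v_bio_k <= u.
    """
    coupling = coupling or model.coupling_config or CouplingConfig()
    model.coupling_config = coupling
    rows: list[LinearConstraint] = []
    for tag, rxn_ids in model.member_reactions.items():
        bio = model.member_biomass[tag]
        for rid in rxn_ids:
            if rid == bio:
                continue
            rows.append(
                LinearConstraint(
                    coefficients={rid: 1.0, bio: -coupling.c},
                    bound=coupling.u,
                    name=f"cpl_up{TAG_SEP}{rid}",
                )
            )
            rows.append(
                LinearConstraint(
                    coefficients={rid: -1.0, bio: -coupling.c},
                    bound=coupling.u,
                    name=f"cpl_lo{TAG_SEP}{rid}",
                )
            )
    model.coupling = rows
    return model


def apply_diet(
    model: CommunityModel,
    diet: DietSpec,
    gap_fill: bool = False,
    trace_metabolites: list[str] | None = None,
    trace_bound: float = DEFAULT_TRACE_BOUND,
) -> CommunityModel:
    """Return a copy of the community with diet exchange bounds set.

    The diet exchange of metabolite m gets import bound lb = -flux(m)
    (export side stays closed); diet exchanges for metabolites absent
    from the diet remain closed unless ``gap_fill`` opens a configured
    trace set at ``trace_bound``.  Diet entries that resolve to no lumen
    metabolite are reported with a warning and listed in
    ``unresolved_diet``.
    """
    out = model.copy()
    out.diet_name = diet.name
    known = set(out.lumen_bases)
    unresolved = sorted(set(diet.fluxes) - known)
    if unresolved:
        warnings.warn(
            f"diet {diet.name!r}: metabolites not present in the community lumen: "
            f"{unresolved}",
            stacklevel=2,
        )
    out.unresolved_diet = unresolved
    trace = set(trace_metabolites or []) if gap_fill else set()
    for base in out.lumen_bases:
        rxn = out.reactions[out.diet_exchange_id(base)]
        flux = diet.fluxes.get(base, 0.0)
        if flux > 0:
            rxn.lower_bound = -flux
        elif base in trace:
            rxn.lower_bound = -trace_bound
        else:
            rxn.lower_bound = 0.0
        rxn.upper_bound = 0.0
    return out
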