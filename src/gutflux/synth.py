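"""Synthetic toy fixtures with known ground truth.

Everything the pipeline consumes can be generated here without
downloads: small fermenter taxon models with declared substrate/product
stoichiometry, Dirichlet-distributed cohort abundances with lognormal
coverage noise, and a miniature food-composition database paired with a
verbatim transcription of a published national food-intake table.

The six taxon templates mirror the producer roles commonly reported for
the human gut community:

==================  =====================  =============================
template            genus (synthetic)      role
==================  =====================  =============================
acetogen            Blautia                glucose -> 2 acetate
propionogen         Bacteroides            glucose -> 2 propionate
butyrogen           Faecalibacterium       glucose -> butyrate, with an
                                           acetate cross-feeding route
isobutyrogen        Phocaeicola            valine -> isobutyrate
                                           (branched-chain fermentation)
mos_utilizer        Bifidobacterium        manno-oligosaccharide (MOS)
                                           hydrolysis and fermentation
generalist          Escherichia            glucose -> acetate (low
                                           yield), maltodextrin use
==================  =====================  =============================

Each template grows on the fixture diet (biomass drawn from glucose) and
its declared capabilities are exactly what standalone FBA recovers, so
cohort-level producer/responder calls have an unambiguous ground truth.
The toys make no attempt at elemental mass balance; stoichiometric
yields are nominal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import CommunityModel, apply_diet, build_community
from .core import DEFAULT_BOUND, LinearConstraint, Metabolite, Reaction, TaxonModel, Taxonomy
from .diet import DEFAULT_DRI, DietSpec, FoodComposition, FoodItem, build_diet_fluxes

#: Molecular weights (g/mol) for all fixture metabolites.
MOLECULAR_WEIGHTS = {
    "glc": 180.16,  # glucose
    "man": 180.16,  # mannose
    "val": 117.15,  # valine
    "ac": 60.05,  # acetate
    "ppa": 74.08,  # propionate
    "but": 88.11,  # butyrate
    "ibut": 88.11,  # isobutyrate
    "mos": 504.44,  # manno-oligosaccharide (mannotriose)
    "mdx": 504.44,  # maltodextrin (triose-equivalent unit)
}

MET_NAMES = {
    "glc": "glucose",
    "man": "mannose",
    "val": "valine",
    "ac": "acetate",
    "ppa": "propionate",
    "but": "butyrate",
    "ibut": "isobutyrate",
    "mos": "manno-oligosaccharide",
    "mdx": "maltodextrin",
}

SCFA_TARGETS = ["ac", "ppa", "but", "ibut"]

#: Grams of biomass-precursor glucose consumed per unit biomass flux.
BIOMASS_GLC_DEMAND = 0.1


@dataclass(frozen=True)
class TaxonTemplate:
    """Declared blueprint of one toy fermenter."""

    name: str
    taxonomy: Taxonomy
    substrates: tuple[str, ...]  # extracellular metabolites it can take up
    products_on_base_diet: tuple[str, ...]  # exportable given glc+val diet
    extra_products: tuple[str, ...] = ()  # exportable only with extra substrates


def _tax(phylum, family, genus, species) -> Taxonomy:
    return Taxonomy(phylum=phylum, family=family, genus=genus, species=species)


TEMPLATES: dict[str, TaxonTemplate] = {
    t.name: t
    for t in [
        TaxonTemplate(
            "acetogen",
            _tax("Bacillota", "Lachnospiraceae", "Blautia", "Blautia synthetica"),
            substrates=("glc",),
            products_on_base_diet=("ac",),
        ),
        TaxonTemplate(
            "propionogen",
            _tax("Bacteroidota", "Bacteroidaceae", "Bacteroides", "Bacteroides syntheticus"),
            substrates=("glc",),
            products_on_base_diet=("ppa",),
        ),
        TaxonTemplate(
            "butyrogen",
            _tax("Bacillota", "Oscillospiraceae", "Faecalibacterium",
                 "Faecalibacterium syntheticum"),
            substrates=("glc", "ac"),
            products_on_base_diet=("but",),
        ),
        TaxonTemplate(
            "isobutyrogen",
            _tax("Bacteroidota", "Bacteroidaceae", "Phocaeicola", "Phocaeicola syntheticus"),
            substrates=("glc", "val"),
            products_on_base_diet=("ibut",),
        ),
        TaxonTemplate(
            "mos_utilizer",
            _tax("Actinomycetota", "Bifidobacteriaceae", "Bifidobacterium",
                 "Bifidobacterium syntheticum"),
            substrates=("glc", "mos"),
            products_on_base_diet=(),
            extra_products=("ac",),
        ),
        TaxonTemplate(
            "generalist",
            _tax("Pseudomonadota", "Enterobacteriaceae", "Escherichia",
                 "Escherichia synthetica"),
            substrates=("glc", "mdx"),
            products_on_base_diet=("ac",),
        ),
    ]
}


def _add_ext_pair(model: TaxonModel, base: str) -> None:
    """Declare base[e] + base[c] with molecular weight and an open exchange."""
    for comp in ("e", "c"):
        mid = f"{base}[{comp}]"
        if mid not in model.metabolites:
            model.add_metabolite(
                Metabolite(
                    id=mid,
                    name=MET_NAMES.get(base, base),
                    compartment=comp,
                    molecular_weight=MOLECULAR_WEIGHTS.get(base),
                )
            )
    ex_id = f"EX_{base}"
    if ex_id not in model.reactions:
        model.add_reaction(
            Reaction(
                id=ex_id,
                stoichiometry={f"{base}[e]": -1.0},
                lower_bound=-DEFAULT_BOUND,
                upper_bound=DEFAULT_BOUND,
                kind="exchange",
            )
        )


def _add_transport(model: TaxonModel, base: str, direction: str) -> None:
    """Irreversible transport; direction 'in' = e->c, 'out' = c->e."""
    if direction == "in":
        rid, stoich = f"T_{base}_in", {f"{base}[e]": -1.0, f"{base}[c]": 1.0}
    else:
        rid, stoich = f"T_{base}_out", {f"{base}[c]": -1.0, f"{base}[e]": 1.0}
    model.add_reaction(
        Reaction(id=rid, stoichiometry=stoich, lower_bound=0.0,
                 upper_bound=DEFAULT_BOUND, kind="transport")
    )


def _add_biomass(model: TaxonModel) -> None:
    model.add_metabolite(Metabolite(id="biomass[c]", name="biomass", compartment="c"))
    model.add_reaction(
        Reaction(
            id="biomass",
            stoichiometry={"glc[c]": -BIOMASS_GLC_DEMAND, "biomass[c]": 1.0},
            lower_bound=0.0,
            upper_bound=DEFAULT_BOUND,
            kind="biomass",
        )
    )
    model.add_reaction(
        Reaction(
            id="EX_biomass",
            stoichiometry={"biomass[c]": -1.0},
            lower_bound=0.0,
            upper_bound=DEFAULT_BOUND,
            kind="exchange",
        )
    )
    model.biomass_reaction_id = "biomass"


def _internal(model: TaxonModel, rid: str, stoich: dict[str, float]) -> None:
    model.add_reaction(
        Reaction(id=rid, stoichiometry=stoich, lower_bound=0.0,
                 upper_bound=DEFAULT_BOUND, kind="internal")
    )


def make_taxon_model(template: TaxonTemplate | str, seed: int = 0) -> TaxonModel:
    """Instantiate a template as a validated TaxonModel.

    Construction is fully deterministic for a given (template, seed);
    the seed is accepted for interface uniformity with the stochastic
    generators.
    """
    if isinstance(template, str):
        template = TEMPLATES[template]
    m = TaxonModel(model_id=template.name, taxonomy=template.taxonomy)
    name = template.name

    _add_ext_pair(m, "glc")
    _add_transport(m, "glc", "in")
    if name == "acetogen":
        _add_ext_pair(m, "ac")
        _internal(m, "ferm_ac", {"glc[c]": -1.0, "ac[c]": 2.0})
        _add_transport(m, "ac", "out")
    elif name == "propionogen":
        _add_ext_pair(m, "ppa")
        _internal(m, "ferm_ppa", {"glc[c]": -1.0, "ppa[c]": 2.0})
        _add_transport(m, "ppa", "out")
    elif name == "butyrogen":
        _add_ext_pair(m, "but")
        _add_ext_pair(m, "ac")
        _internal(m, "ferm_but", {"glc[c]": -1.0, "but[c]": 1.0})
        # cross-feeding route: acetate boosts butyrate yield
        _internal(m, "ferm_but_ac", {"glc[c]": -1.0, "ac[c]": -1.0, "but[c]": 1.8})
        _add_transport(m, "ac", "in")
        _add_transport(m, "but", "out")
    elif name == "isobutyrogen":
        _add_ext_pair(m, "val")
        _add_ext_pair(m, "ibut")
        _internal(m, "ferm_ibut", {"val[c]": -1.0, "ibut[c]": 1.0})
        _add_transport(m, "val", "in")
        _add_transport(m, "ibut", "out")
    elif name == "mos_utilizer":
        _add_ext_pair(m, "mos")
        _add_ext_pair(m, "ac")
        m.add_metabolite(
            Metabolite(id="man[c]", name="mannose", compartment="c",
                       molecular_weight=MOLECULAR_WEIGHTS["man"])
        )
        _internal(m, "mos_hydrolase", {"mos[c]": -1.0, "man[c]": 3.0})
        _internal(m, "ferm_man", {"man[c]": -1.0, "ac[c]": 2.0})
        _add_transport(m, "mos", "in")
        _add_transport(m, "ac", "out")
    elif name == "generalist":
        _add_ext_pair(m, "ac")
        _add_ext_pair(m, "mdx")
        _internal(m, "ferm_ac_lowyield", {"glc[c]": -1.0, "ac[c]": 1.0})
        _internal(m, "mdx_hydrolase", {"mdx[c]": -1.0, "glc[c]": 3.0})
        _add_transport(m, "mdx", "in")
        _add_transport(m, "ac", "out")
    else:
        raise KeyError(f"unknown template {name!r}")
    _add_biomass(m)
    return m


def default_templates() -> list[str]:
    return list(TEMPLATES)


def taxonomy_table(templates: list[str] | None = None) -> pd.DataFrame:
    """Taxonomy lookup (model_id -> phylum/family/genus/species)."""
    names = templates or default_templates()
    rows = {n: TEMPLATES[n].taxonomy.as_dict() for n in names}
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("model_id")


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass
class CohortGroundTruth:
    """What the generator actually put into a synthetic cohort."""

    abundances: pd.DataFrame  # models x samples, the drawn Dirichlet fractions
    producers: dict[str, set[str]]  # metabolite -> genus set (base diet)
    substrate_consumers: dict[str, set[str]]  # substrate -> genus set
    seed: int
    dirichlet_alpha: float
    noise_sd: float

    def as_dict(self) -> dict:
        return {
            "seed": self.seed,
            "dirichlet_alpha": self.dirichlet_alpha,
            "noise_sd": self.noise_sd,
            "producers": {m: sorted(g) for m, g in self.producers.items()},
            "substrate_consumers": {
                m: sorted(g) for m, g in self.substrate_consumers.items()
            },
        }


def ground_truth_capabilities(
    templates: list[str] | None = None,
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """Declared producer and consumer sets at genus level."""
    names = templates or default_templates()
    producers: dict[str, set[str]] = {}
    consumers: dict[str, set[str]] = {}
    for n in names:
        t = TEMPLATES[n]
        for met in t.products_on_base_diet:
            producers.setdefault(met, set()).add(t.taxonomy.genus)
        for sub in t.substrates:
            consumers.setdefault(sub, set()).add(t.taxonomy.genus)
    return producers, consumers


def make_cohort(
    n_samples: int = 10,
    templates: list[str] | None = None,
    dirichlet_alpha: float = 5.0,
    seed: int = 0,
    depth: float = 1000.0,
    noise_sd: float = 0.1,
) -> tuple[pd.DataFrame, CohortGroundTruth]:
    """Draw a synthetic cohort: Dirichlet abundances -> noisy coverages.

    Returns (coverage table models x samples, ground truth).  The
    coverage of taxon i in a sample is ``abundance_i * depth`` perturbed
    by multiplicative lognormal noise with log-sd ``noise_sd``; the seed
    fully determines every byte of the output.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if dirichlet_alpha <= 0:
        raise ValueError("dirichlet_alpha must be > 0")
    names = templates or default_templates()
    rng = np.random.default_rng(seed)
    k = len(names)
    samples = [f"sample_{i + 1:02d}" for i in range(n_samples)]
    abund = rng.dirichlet(np.full(k, dirichlet_alpha), size=n_samples)  # n x k
    noise = rng.lognormal(mean=0.0, sigma=noise_sd, size=(n_samples, k))
    coverage = pd.DataFrame((abund * noise * depth).T, index=names, columns=samples)
    coverage.index.name = "model_id"
    abundances = pd.DataFrame(abund.T, index=names, columns=samples)
    producers, consumers = ground_truth_capabilities(names)
    truth = CohortGroundTruth(
        abundances=abundances,
        producers=producers,
        substrate_consumers=consumers,
        seed=seed,
        dirichlet_alpha=dirichlet_alpha,
        noise_sd=noise_sd,
    )
    return coverage, truth


# ---------------------------------------------------------------------------
# Food fixtures
# ---------------------------------------------------------------------------

#: Verbatim transcription of a published national food-intake table:
#: (food item, mean g/day, sd g/day, matched against the primary
#: composition database?).
INTAKE_TABLE_ROWS: list[tuple[str, float, float, str]] = [
    ("Rice", 262.53, 46.01, "Matched"),
    ("Dumpling", 68.12, 12.58, "Unmatched"),
    ("Sandwich", 60.12, 7.80, "Matched"),
    ("Sweet potato", 69.12, 10.23, "Matched"),
    ("Peanuts", 54.78, 7.50, "Matched"),
    ("Cowpeas", 33.33, 5.41, "Matched"),
    ("Mushrooms", 29.96, 4.63, "Matched"),
    ("Pickled cabbage", 24.67, 4.07, "Matched"),
    ("Watermelon", 202.27, 29.06, "Matched"),
    ("Snacks, banana chips", 25.00, 4.20, "Matched"),
    ("Egg", 55.42, 4.94, "Matched"),
    ("Pork", 31.02, 5.45, "Matched"),
    ("Pork meatball", 62.75, 11.53, "Unmatched"),
    ("Fish, tilapia", 64.43, 12.60, "Matched"),
    ("Fish, mackerel", 30.37, 5.23, "Matched"),
    ("Insect, cricket", 22.26, 4.45, "Unmatched"),
    ("Milk", 241.01, 32.73, "Matched"),
    ("Ice cream", 62.36, 4.65, "Matched"),
    ("Beer", 454.17, 301.01, "Matched"),
    ("Snacks, potato chips", 22.88, 5.45, "Matched"),
    ("Thai dessert (Khao Tom Mud)", 88.66, 11.42, "Unmatched"),
    ("Sugar", 6.37, 1.11, "Matched"),
    ("Oil, palm", 9.81, 1.22, "Matched"),
    ("Fish sauce", 5.37, 0.78, "Unmatched"),
    ("Chicken essence", 47.57, 4.87, "Unmatched"),
]

# Synthetic per-food compositions: metabolite mg per 100 g (glucose stands
# in for available carbohydrate, valine for fermentable protein-derived
# branched-chain amino acid) and macros in g per 100 g.  Values are
# plausible-magnitude stand-ins, not database extracts.
_PRIMARY_COMPOSITION = {
    "Rice": ({"glc": 28000.0}, {"carbohydrate": 28.0, "protein": 2.7, "fat": 0.3}),
    "Sandwich": ({"glc": 45000.0, "val": 400.0},
                 {"carbohydrate": 45.0, "protein": 8.0, "fat": 4.0}),
    "Sweet potato": ({"glc": 20000.0}, {"carbohydrate": 20.0, "protein": 1.6, "fat": 0.1}),
    "Peanuts": ({"glc": 4000.0, "val": 1100.0},
                {"carbohydrate": 16.1, "protein": 25.8, "fat": 49.2}),
    "Cowpeas": ({"glc": 15000.0, "val": 1100.0},
                {"carbohydrate": 60.0, "protein": 23.5, "fat": 1.3}),
    "Mushrooms": ({"glc": 3300.0, "val": 230.0},
                  {"carbohydrate": 3.3, "protein": 3.1, "fat": 0.3}),
    "Pickled cabbage": ({"glc": 2000.0}, {"carbohydrate": 2.0, "protein": 1.0, "fat": 0.1}),
    "Watermelon": ({"glc": 7500.0}, {"carbohydrate": 7.5, "protein": 0.6, "fat": 0.2}),
    "Snacks, banana chips": ({"glc": 50000.0},
                             {"carbohydrate": 50.0, "protein": 2.3, "fat": 33.0}),
    "Egg": ({"glc": 700.0, "val": 850.0}, {"carbohydrate": 0.7, "protein": 12.6, "fat": 9.5}),
    "Pork": ({"val": 1200.0}, {"protein": 21.0, "fat": 10.0}),
    "Fish, tilapia": ({"val": 1100.0}, {"protein": 20.0, "fat": 1.7}),
    "Fish, mackerel": ({"val": 1300.0}, {"protein": 19.0, "fat": 13.4}),
    "Milk": ({"glc": 5000.0, "val": 220.0},
             {"carbohydrate": 5.0, "protein": 3.3, "fat": 3.3}),
    "Ice cream": ({"glc": 23000.0, "val": 150.0},
                  {"carbohydrate": 23.0, "protein": 3.5, "fat": 11.0}),
    "Beer": ({"glc": 3600.0}, {"carbohydrate": 3.6, "protein": 0.5, "alcohol": 4.7}),
    "Snacks, potato chips": ({"glc": 50000.0, "val": 300.0},
                             {"carbohydrate": 50.0, "protein": 6.6, "fat": 34.0}),
    "Sugar": ({"glc": 99800.0}, {"carbohydrate": 99.8}),
    "Oil, palm": ({}, {"fat": 100.0}),
}

# Manually curated entries for two traditional foods missing from the
# primary database (the manual-calculation path).
_MANUAL_COMPOSITION = {
    "Dumpling": ({"glc": 25000.0, "val": 500.0},
                 {"carbohydrate": 25.0, "protein": 9.0, "fat": 8.0}),
    "Pork meatball": ({"glc": 6000.0, "val": 900.0},
                      {"carbohydrate": 6.0, "protein": 15.0, "fat": 14.0}),
}


@dataclass
class FoodDB:
    intake: list[FoodItem]
    intake_table: pd.DataFrame
    composition: FoodComposition
    manual_composition: FoodComposition
    molecular_weights: dict[str, float]
    dri: dict


def make_food_db(seed: int = 0) -> FoodDB:
    """The bundled food fixture: intake transcription + synthetic
    compositions + molecular weights + DRI reference ranges.

    The fixture is static; ``seed`` is accepted for interface uniformity.
    """
    intake = [
        FoodItem(name=n, intake=g, intake_sd=sd,
                 composition_source="primary_db" if s == "Matched" else "unmatched")
        for n, g, sd, s in INTAKE_TABLE_ROWS
    ]
    table = pd.DataFrame(
        INTAKE_TABLE_ROWS, columns=["name", "g_per_day", "sd", "vmh_status"]
    )
    comp = FoodComposition()
    for food, (mets, macros) in _PRIMARY_COMPOSITION.items():
        comp.add(food, mets, macros)
    manual = FoodComposition()
    for food, (mets, macros) in _MANUAL_COMPOSITION.items():
        manual.add(food, mets, macros)
    return FoodDB(
        intake=intake,
        intake_table=table,
        composition=comp,
        manual_composition=manual,
        molecular_weights=dict(MOLECULAR_WEIGHTS),
        dri=dict(DEFAULT_DRI),
    )


def fixture_diet(food_db: FoodDB | None = None, name: str = "average_diet") -> DietSpec:
    """The base diet every template grows on (glucose + valine support)."""
    db = food_db or make_food_db()
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")  # unmatched fixture foods are expected
        return build_diet_fluxes(
            db.intake, db.composition, db.molecular_weights,
            manual_composition=db.manual_composition, name=name,
        )


def supplement_arms(base: DietSpec, food_db: FoodDB | None = None) -> tuple[DietSpec, DietSpec]:
    """(placebo, prebiotic) arms: 10 g/day maltodextrin vs 5 g/day MOS
    plus 5 g/day maltodextrin on top of the base diet."""
    from .diet import add_supplement

    db = food_db or make_food_db()
    placebo = add_supplement(base, {"mdx": 10.0}, None, db.molecular_weights,
                             name=f"{base.name}+placebo")
    prebiotic = add_supplement(base, {"mos": 5.0, "mdx": 5.0}, None,
                               db.molecular_weights, name=f"{base.name}+mos")
    return placebo, prebiotic


# ---------------------------------------------------------------------------
# Hand-checkable toy networks (vertex-enumeration scale)
# ---------------------------------------------------------------------------

_TOY_BOUND = 1000.0


def toy_chain() -> TaxonModel:
    """glc import (<=10) -> glc -> 2 ac -> ac export.  Max EX_ac = 20."""
    m = TaxonModel(model_id="toy_chain")
    m.add_metabolite(Metabolite(id="glc", name="glucose", compartment="c"))
    m.add_metabolite(Metabolite(id="ac", name="acetate", compartment="c"))
    m.add_reaction(Reaction("EX_glc", {"glc": -1.0}, -10.0, _TOY_BOUND, "exchange"))
    m.add_reaction(Reaction("ferm", {"glc": -1.0, "ac": 2.0}, 0.0, _TOY_BOUND, "internal"))
    m.add_reaction(Reaction("EX_ac", {"ac": -1.0}, 0.0, _TOY_BOUND, "exchange"))
    return m


def toy_branched() -> TaxonModel:
    """Glucose split between an acetate and a propionate branch."""
    m = TaxonModel(model_id="toy_branched")
    for mid, name in (("glc", "glucose"), ("ac", "acetate"), ("ppa", "propionate")):
        m.add_metabolite(Metabolite(id=mid, name=name, compartment="c"))
    m.add_reaction(Reaction("EX_glc", {"glc": -1.0}, -10.0, 0.0, "exchange"))
    m.add_reaction(Reaction("ferm_ac", {"glc": -1.0, "ac": 2.0}, 0.0, _TOY_BOUND, "internal"))
    m.add_reaction(Reaction("ferm_ppa", {"glc": -1.0, "ppa": 2.0}, 0.0, _TOY_BOUND, "internal"))
    m.add_reaction(Reaction("EX_ac", {"ac": -1.0}, 0.0, _TOY_BOUND, "exchange"))
    m.add_reaction(Reaction("EX_ppa", {"ppa": -1.0}, 0.0, _TOY_BOUND, "exchange"))
    return m


def toy_coupled() -> TaxonModel:
    """Fermentation coupled to growth: |v_ferm| <= 400 v_bio."""
    m = TaxonModel(model_id="toy_coupled")
    for mid, name in (("glc", "glucose"), ("ac", "acetate"), ("b", "biomass")):
        m.add_metabolite(Metabolite(id=mid, name=name, compartment="c"))
    m.add_reaction(Reaction("EX_glc", {"glc": -1.0}, -10.0, _TOY_BOUND, "exchange"))
    m.add_reaction(Reaction("bio", {"glc": -0.1, "b": 1.0}, 0.0, _TOY_BOUND, "biomass"))
    m.add_reaction(Reaction("EX_b", {"b": -1.0}, 0.0, _TOY_BOUND, "exchange"))
    m.add_reaction(Reaction("ferm", {"glc": -1.0, "ac": 2.0}, 0.0, _TOY_BOUND, "internal"))
    m.add_reaction(Reaction("EX_ac", {"ac": -1.0}, 0.0, _TOY_BOUND, "exchange"))
    m.biomass_reaction_id = "bio"
    m.coupling = [
        LinearConstraint({"ferm": 1.0, "bio": -400.0}, 0.0, "cpl_up__ferm"),
        LinearConstraint({"ferm": -1.0, "bio": -400.0}, 0.0, "cpl_lo__ferm"),
    ]
    return m


def toy_models() -> dict[str, TaxonModel]:
    """The bundled hand-checkable toys for oracle comparisons."""
    return {"chain": toy_chain(), "branched": toy_branched(), "coupled": toy_coupled()}


def mini_fermenter() -> TaxonModel:
    """A minimal compartmented fermenter (glc -> 2 ac) used to build the
    pass-through toy community."""
    m = TaxonModel(model_id="mini")
    _add_ext_pair(m, "glc")
    _add_ext_pair(m, "ac")
    _add_transport(m, "glc", "in")
    _internal(m, "ferm", {"glc[c]": -1.0, "ac[c]": 2.0})
    _add_transport(m, "ac", "out")
    _add_biomass(m)
    return m


def toy_passthrough_community(glc_flux: float = 10.0) -> CommunityModel:
    """Single mini fermenter in the community scaffold, diet glc = 10.

    Built without coupling and with relaxed community-biomass bounds so
    the hand-LP identities hold exactly: glucose can pass straight
    through the lumen (net secretion 0) and maximal acetate secretion is
    yield x import bound = 2 * glc_flux.
    """
    cm = build_community(
        [mini_fermenter()],
        {"mini": 1.0},
        couple=False,
        biomass_bounds=(0.0, DEFAULT_BOUND),
    )
    diet = DietSpec(name="toy_diet", fluxes={"glc": glc_flux})
    return apply_diet(cm, diet)
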