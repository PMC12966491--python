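"""Translate food-intake tables into metabolite uptake-flux vectors.

A national food-consumption survey reports intake in g/day per food item;
a food-composition database reports metabolite content in mg per 100 g
edible portion plus macronutrients in g per 100 g.  The conversion to a
diet flux vector is

    flux(m) [mmol/day] = sum_over_foods  intake_g_per_day
                         * mg_per_100g(m) / 100  / MW(m) [g/mol]

(mg divided by g/mol gives mmol).  Foods missing from the primary
composition database can be covered by a secondary, manually curated
database; fluxes from both sources are summed.  Foods matched by neither
are excluded but retained in the diet's provenance record.

The module also profiles dietary energy via Atwater-style factors and
checks the profile against dietary-reference-intake (DRI) ranges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

#: kcal released per gram of macronutrient (Atwater factors; alcohol 7).
DEFAULT_ENERGY_FACTORS = {"carbohydrate": 4.0, "fat": 9.0, "protein": 4.0, "alcohol": 7.0}

#: Default DRI reference ranges: energy in kcal/day, macronutrient shares in
#: percent of total energy.  Protein carries an additional cautionary upper
#: threshold above its recommended range.
DEFAULT_DRI = {
    "energy_kcal": (1500.0, 2400.0),
    "carbohydrate_pct": (45.0, 65.0),
    "fat_pct": (20.0, 35.0),
    "protein_pct": (10.0, 15.0),
    "protein_caution_pct": 30.0,
}

MACROS = ("carbohydrate", "fat", "protein", "alcohol")


class DietError(Exception):
    pass


@dataclass
class FoodItem:
    name: str
    intake: float  # g/day
    intake_sd: float | None = None
    composition_source: str = "primary_db"  # primary_db | manual_db | unmatched

    def __post_init__(self):
        if self.intake < 0:
            raise DietError(f"negative intake for {self.name!r}")


class FoodComposition:
    """food name -> metabolite content (mg/100 g) and macros (g/100 g)."""

    def __init__(self, entries: dict[str, dict] | None = None):
        # entry: {"metabolites": {met_id: mg_per_100g}, "macros": {macro: g_per_100g}}
        self.entries: dict[str, dict] = {}
        for food, entry in (entries or {}).items():
            self.add(food, entry.get("metabolites", {}), entry.get("macros", {}))

    def add(self, food: str, metabolites: dict[str, float], macros: dict[str, float]):
        for v in list(metabolites.values()) + list(macros.values()):
            if v < 0:
                raise DietError(f"negative composition value for {food!r}")
        self.entries[food] = {
            "metabolites": dict(metabolites),
            "macros": {m: float(macros.get(m, 0.0)) for m in MACROS},
        }

    def __contains__(self, food: str) -> bool:
        return food in self.entries

    def metabolites(self, food: str) -> dict[str, float]:
        return self.entries[food]["metabolites"]

    def macros(self, food: str) -> dict[str, float]:
        return self.entries[food]["macros"]


@dataclass
class DietSpec:
    """A named diet condition: metabolite id -> uptake flux in mmol/day."""

    name: str
    fluxes: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        bad = [m for m, f in self.fluxes.items() if f < 0]
        if bad:
            raise DietError(f"negative diet fluxes for {bad}")

    @property
    def support(self) -> set[str]:
        return {m for m, f in self.fluxes.items() if f > 0}

    def copy(self, name: str | None = None) -> "DietSpec":
        return DietSpec(
            name=name or self.name, fluxes=dict(self.fluxes), provenance=dict(self.provenance)
        )


@dataclass
class MacroProfile:
    energy: float  # kcal/day
    pct_carbohydrate: float
    pct_fat: float
    pct_protein: float
    pct_alcohol: float = 0.0


@dataclass
class DriCheck:
    name: str
    observed: float
    low: float
    high: float
    verdict: str  # within | below | above | above-but-below-caution
    caution: float | None = None


@dataclass
class DriReport:
    checks: list[DriCheck]

    def verdict(self, name: str) -> str:
        for c in self.checks:
            if c.name == name:
                return c.verdict
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "check": c.name,
                    "observed": c.observed,
                    "low": c.low,
                    "high": c.high,
                    "caution": c.caution,
                    "verdict": c.verdict,
                }
                for c in self.checks
            ]
        )


def build_diet_fluxes(
    intake: list[FoodItem],
    composition: FoodComposition,
    molecular_weights: dict[str, float],
    manual_composition: FoodComposition | None = None,
    name: str = "diet",
) -> DietSpec:
    """Convert an intake table plus composition databases into a DietSpec.

    The primary database is consulted first; foods absent from it fall
    back to the manual database; foods matched by neither are excluded
    with a warning and recorded as ``unmatched`` in provenance.  A
    metabolite without a molecular weight raises, naming the metabolite.
    """
    fluxes: dict[str, float] = {}
    provenance: dict[str, str] = {}
    for item in intake:
        if item.name in composition:
            source, db = "primary_db", composition
        elif manual_composition is not None and item.name in manual_composition:
            source, db = "manual_db", manual_composition
        else:
            provenance[item.name] = "unmatched"
            if item.intake > 0:
                warnings.warn(
                    f"food {item.name!r} has no composition entry; excluded from diet",
                    stacklevel=2,
                )
            continue
        provenance[item.name] = source
        for met, mg_per_100g in db.metabolites(item.name).items():
            if met not in molecular_weights:
                raise DietError(f"no molecular weight for metabolite {met!r}")
            mmol = item.intake * (mg_per_100g / 100.0) / molecular_weights[met]
            fluxes[met] = fluxes.get(met, 0.0) + mmol
    return DietSpec(name=name, fluxes=fluxes, provenance=provenance)


def macronutrient_profile(
    intake: list[FoodItem],
    composition: FoodComposition,
    manual_composition: FoodComposition | None = None,
    energy_factors: dict[str, float] | None = None,
) -> MacroProfile:
    """Total dietary energy and the % of energy from each macronutrient."""
    factors = dict(DEFAULT_ENERGY_FACTORS)
    factors.update(energy_factors or {})
    grams = {m: 0.0 for m in MACROS}
    for item in intake:
        if item.name in composition:
            macros = composition.macros(item.name)
        elif manual_composition is not None and item.name in manual_composition:
            macros = manual_composition.macros(item.name)
        else:
            continue
        for m in MACROS:
            grams[m] += item.intake * macros.get(m, 0.0) / 100.0
    energy_by_macro = {m: grams[m] * factors[m] for m in MACROS}
    energy = sum(energy_by_macro.values())
    if energy <= 0:
        raise DietError("total dietary energy is zero; macronutrient shares undefined")
    pct = {m: energy_by_macro[m] / energy * 100.0 for m in MACROS}
    return MacroProfile(
        energy=energy,
        pct_carbohydrate=pct["carbohydrate"],
        pct_fat=pct["fat"],
        pct_protein=pct["protein"],
        pct_alcohol=pct["alcohol"],
    )


def _range_verdict(value: float, low: float, high: float, caution: float | None = None) -> str:
    if value < low:
        return "below"
    if value <= high:
        return "within"
    if caution is not None and value < caution:
        return "above-but-below-caution"
    return "above"


def validate_dri(profile: MacroProfile, reference: dict | None = None) -> DriReport:
    """Check a macronutrient profile against DRI reference ranges.

    Energy, carbohydrate and fat get a three-way verdict
    (below/within/above); protein additionally distinguishes exceeding
    its recommended range while remaining below the cautionary threshold.
    """
    ref = dict(DEFAULT_DRI)
    ref.update(reference or {})
    checks = []
    for name, value, key, caution_key in (
        ("energy", profile.energy, "energy_kcal", None),
        ("carbohydrate", profile.pct_carbohydrate, "carbohydrate_pct", None),
        ("fat", profile.pct_fat, "fat_pct", None),
        ("protein", profile.pct_protein, "protein_pct", "protein_caution_pct"),
    ):
        low, high = ref[key]
        if not (low <= high) or not all(map(lambda x: x == x, (low, high))):
            raise DietError(f"invalid DRI range for {key}: ({low}, {high})")
        caution = ref.get(caution_key) if caution_key else None
        checks.append(
            DriCheck(
                name=name,
                observed=value,
                low=low,
                high=high,
                caution=caution,
                verdict=_range_verdict(value, low, high, caution),
            )
        )
    return DriReport(checks)


def add_supplement(
    base: DietSpec,
    supplement: dict[str, float],
    composition: FoodComposition | None,
    molecular_weights: dict[str, float],
    name: str | None = None,
) -> DietSpec:
    """Add supplement doses (grams/day) on top of a base diet.

    Each key is resolved first as a metabolite id (grams converted to
    mmol/day via its molecular weight) and otherwise as a food name in the
    composition database.  The base diet is left unmodified.
    """
    out = base.copy(name=name or base.name)
    for component, grams in supplement.items():
        if grams < 0:
            raise DietError(f"negative supplement dose for {component!r}")
        if grams == 0:
            continue
        if component in molecular_weights:
            out.fluxes[component] = (
                out.fluxes.get(component, 0.0) + grams * 1000.0 / molecular_weights[component]
            )
        elif composition is not None and component in composition:
            for met, mg_per_100g in composition.metabolites(component).items():
                if met not in molecular_weights:
                    raise DietError(f"no molecular weight for metabolite {met!r}")
                out.fluxes[met] = (
                    out.fluxes.get(met, 0.0)
                    + grams * (mg_per_100g / 100.0) / molecular_weights[met]
                )
        else:
            raise DietError(f"unknown supplement component {component!r}")
    return out


def compare_diets(diets: list[DietSpec], threshold: float = 1.0) -> pd.DataFrame:
    """Per-metabolite presence across diets, the shared set, and the subset
    exceeding ``threshold`` mmol/day in every diet.

    Returns a DataFrame indexed by metabolite with one boolean presence
    column per diet plus ``shared`` and ``exceeds_threshold_everywhere``;
    the shared/exceeding sets are also attached in ``DataFrame.attrs``.
    """
    if len(diets) < 2:
        raise DietError("compare_diets needs at least two diets")
    all_mets = sorted(set().union(*(d.support for d in diets)))
    rows = []
    for met in all_mets:
        presence = {d.name: met in d.support for d in diets}
        rows.append(
            {
                "metabolite": met,
                **presence,
                "shared": all(presence.values()),
                "exceeds_threshold_everywhere": all(
                    d.fluxes.get(met, 0.0) > threshold for d in diets
                ),
            }
        )
    df = pd.DataFrame(rows).set_index("metabolite") if rows else pd.DataFrame(
        columns=[d.name for d in diets] + ["shared", "exceeds_threshold_everywhere"]
    )
    df.attrs["shared"] = {m for m in all_mets if df.loc[m, "shared"]} if rows else set()
    df.attrs["exceeds_everywhere"] = (
        {m for m in all_mets if df.loc[m, "exceeds_threshold_everywhere"]} if rows else set()
    )
    df.attrs["threshold"] = threshold
    return df


def read_intake_tsv(path) -> list[FoodItem]:
    """Read an intake table TSV with columns name, g_per_day[, sd, source]."""
    df = pd.read_csv(path, sep="\t")
    items = []
    for _, row in df.iterrows():
        items.append(
            FoodItem(
                name=str(row["name"]),
                intake=float(row["g_per_day"]),
                intake_sd=float(row["sd"]) if "sd" in df.columns and pd.notna(row["sd"]) else None,
                composition_source=str(row["source"]) if "source" in df.columns else "primary_db",
            )
        )
    return items
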