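"""Model and table serialization.

Two model formats are supported:

* a JSON dialect (documented in ``docs/methods.md``) that round-trips every
  field of :class:`~gutflux.core.TaxonModel` and, for community models, the
  coupling-constraint block;
* SBML Level 3 with the FBC package, read and written through cobrapy for
  interoperability with published reconstruction resources.  SBML carries
  no reaction ``kind`` or taxonomy metadata; kinds are re-inferred on load
  (single-metabolite boundary reactions become exchanges, the FBC objective
  becomes the biomass reaction).

Tabular formats (TSV via pandas) cover diet vectors, coverage tables,
taxonomy lookups and the result tables written by the CLI.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .core import (
    DEFAULT_BOUND,
    LinearConstraint,
    Metabolite,
    ModelError,
    Reaction,
    TaxonModel,
    Taxonomy,
    require_valid,
)

JSON_DIALECT_VERSION = 1


def model_to_dict(model: TaxonModel) -> dict:
    d: dict = {
        "dialect_version": JSON_DIALECT_VERSION,
        "model_id": model.model_id,
        "biomass_reaction_id": model.biomass_reaction_id,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                **(
                    {"molecular_weight": m.molecular_weight}
                    if m.molecular_weight is not None
                    else {}
                ),
            }
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "kind": r.kind,
            }
            for r in model.reactions.values()
        ],
    }
    if model.taxonomy is not None:
        d["taxonomy"] = model.taxonomy.as_dict()
    # Community extras (duck-typed: present only on CommunityModel)
    coupling = getattr(model, "coupling", None)
    if coupling is not None:
        cfg = getattr(model, "coupling_config", None)
        d["community"] = {
            "members": getattr(model, "members", {}),
            "abundances": getattr(model, "abundances", {}),
            "member_biomass": getattr(model, "member_biomass", {}),
            "member_reactions": getattr(model, "member_reactions", {}),
            "lumen_bases": getattr(model, "lumen_bases", []),
            "diet_name": getattr(model, "diet_name", None),
            "coupling_config": {"c": cfg.c, "u": cfg.u} if cfg else None,
            "coupling": [
                {"coefficients": c.coefficients, "bound": c.bound, "name": c.name}
                for c in coupling
            ],
        }
    return d


def model_from_dict(d: dict) -> TaxonModel:
    if "community" in d:
        from .community import CommunityModel

        model: TaxonModel = CommunityModel(model_id=d.get("model_id", ""))
    else:
        model = TaxonModel(model_id=d.get("model_id", ""))
    model.biomass_reaction_id = d.get("biomass_reaction_id", "")
    if "taxonomy" in d:
        model.taxonomy = Taxonomy(**d["taxonomy"])
    for m in d.get("metabolites", []):
        if "id" not in m:
            raise ModelError(f"metabolite entry without id: {m!r}")
        model.add_metabolite(
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment", "c"),
                molecular_weight=m.get("molecular_weight"),
            )
        )
    for r in d.get("reactions", []):
        if "id" not in r or "stoichiometry" not in r:
            raise ModelError(f"reaction entry missing id/stoichiometry: {r!r}")
        model.add_reaction(
            Reaction(
                id=r["id"],
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                lower_bound=float(r.get("lower_bound", -DEFAULT_BOUND)),
                upper_bound=float(r.get("upper_bound", DEFAULT_BOUND)),
                kind=r.get("kind", "internal"),
            )
        )
    if "community" in d:
        from .community import CouplingConfig

        c = d["community"]
        model.members = dict(c.get("members", {}))
        model.abundances = {k: float(v) for k, v in c.get("abundances", {}).items()}
        model.member_biomass = dict(c.get("member_biomass", {}))
        model.member_reactions = {
            k: list(v) for k, v in c.get("member_reactions", {}).items()
        }
        model.lumen_bases = list(c.get("lumen_bases", []))
        model.diet_name = c.get("diet_name")
        if c.get("coupling_config"):
            model.coupling_config = CouplingConfig(**c["coupling_config"])
        model.coupling = [
            LinearConstraint(
                coefficients={k: float(v) for k, v in row["coefficients"].items()},
                bound=float(row["bound"]),
                name=row.get("name", ""),
            )
            for row in c.get("coupling", [])
        ]
    return model


# -- SBML bridge (via cobrapy) ----------------------------------------------


def _to_cobra(model: TaxonModel):
    import cobra

    cm = cobra.Model(model.model_id)
    mets = {}
    for m in model.metabolites.values():
        cmet = cobra.Metabolite(m.id, name=m.name, compartment=m.compartment or "c")
        mets[m.id] = cmet
    cm.add_metabolites(list(mets.values()))
    rxns = []
    for r in model.reactions.values():
        crxn = cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        rxns.append(crxn)
    cm.add_reactions(rxns)
    for r in model.reactions.values():
        cm.reactions.get_by_id(r.id).add_metabolites(
            {mets[mid]: coef for mid, coef in r.stoichiometry.items()}
        )
    if model.biomass_reaction_id:
        cm.objective = cm.reactions.get_by_id(model.biomass_reaction_id)
    return cm


def _from_cobra(cm, model_id: str | None = None) -> TaxonModel:
    from cobra.util.solver import linear_reaction_coefficients

    model = TaxonModel(model_id=model_id or cm.id or "model")
    for met in cm.metabolites:
        model.add_metabolite(
            Metabolite(id=met.id, name=met.name or "", compartment=met.compartment or "c")
        )
    objective_ids = {r.id for r in linear_reaction_coefficients(cm)}
    for rxn in cm.reactions:
        stoich = {met.id: coef for met, coef in rxn.metabolites.items()}
        if rxn.id in objective_ids:
            kind = "biomass"
        elif len(stoich) == 1:
            kind = "exchange"
        elif len({cm.metabolites.get_by_id(m).compartment for m in stoich}) > 1:
            kind = "transport"
        else:
            kind = "internal"
        model.add_reaction(
            Reaction(
                id=rxn.id,
                stoichiometry=stoich,
                lower_bound=float(rxn.lower_bound),
                upper_bound=float(rxn.upper_bound),
                kind=kind,
            )
        )
    if objective_ids:
        model.biomass_reaction_id = next(iter(objective_ids))
    return model


# -- public load/save --------------------------------------------------------


def _infer_format(path: Path, format: str | None) -> str:
    if format:
        return format
    suffix = path.suffix.lower()
    if suffix in (".json",):
        return "json"
    if suffix in (".xml", ".sbml"):
        return "sbml"
    raise ValueError(f"cannot infer model format from {path.name!r}; pass format=")


def load_model(path: str | Path, format: str | None = None) -> TaxonModel:
    """Load a taxon (or community) model from JSON or SBML.

    The returned model passes :func:`~gutflux.core.validate_model`;
    malformed files raise :class:`~gutflux.core.ModelError` naming the
    offending element.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        try:
            d = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ModelError(f"{path}: invalid JSON ({exc})") from exc
        model = model_from_dict(d)
    elif fmt == "sbml":
        from cobra.io import read_sbml_model

        model = _from_cobra(read_sbml_model(str(path)))
    else:
        raise ValueError(f"unknown model format {fmt!r}")
    require_valid(model)
    return model


def save_model(model: TaxonModel, path: str | Path, format: str | None = None) -> Path:
    """Write a model to JSON (lossless) or SBML (stoichiometry + bounds)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    require_valid(model)
    if fmt == "json":
        path.write_text(json.dumps(model_to_dict(model), indent=1, ensure_ascii=False))
    elif fmt == "sbml":
        from cobra.io import write_sbml_model

        write_sbml_model(_to_cobra(model), str(path))
    else:
        raise ValueError(f"unknown model format {fmt!r}")
    return path


# -- tabular formats ---------------------------------------------------------


def write_diet_tsv(diet, path: str | Path) -> Path:
    """Serialize a DietSpec as two-column TSV (metabolite_id, mmol_per_day)."""
    path = Path(path)
    df = pd.DataFrame(
        {"metabolite_id": list(diet.fluxes), "mmol_per_day": list(diet.fluxes.values())}
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def read_diet_tsv(path: str | Path, name: str | None = None):
    from .diet import DietSpec

    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    fluxes = dict(zip(df["metabolite_id"].astype(str), df["mmol_per_day"].astype(float)))
    return DietSpec(name=name or path.stem, fluxes=fluxes)


def read_coverage_tsv(path: str | Path) -> pd.DataFrame:
    """Coverage table: rows = model ids, columns = samples (CoverM-style)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_coverage_tsv(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t", index_label="model_id")
    return path


def read_taxonomy_tsv(path: str | Path) -> pd.DataFrame:
    """Taxonomy lookup: model_id index, columns phylum/family/genus/species."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_taxonomy_tsv(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t", index_label="model_id")
    return path
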