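"""Flux variability analysis and net secretion/uptake computation.

FVA solves two LPs per reaction (independent minimization and
maximization over the constrained flux polytope, community biomass
bounds and coupling rows active).  Per-metabolite net fluxes follow the
symmetric convention

    net_secretion(m) = maxFVA(fecal exchange of m) + minFVA(diet exchange of m)
    net_uptake(m)    = maxFVA(diet exchange of m) + minFVA(fecal exchange of m)

under the export-positive sign convention, with a missing exchange
contributing 0.  An alternative magnitude-based convention (secretion
and uptake reported as nonnegative magnitudes of the fecal export and
diet import capacity) is available via ``convention="magnitude"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_BOUND,
    FluxRange,
    InfeasibleError,
    TaxonModel,
    _solve_arrays,
    build_lp_arrays,
)
from .community import CommunityModel, CouplingConfig, apply_diet, build_community
from .diet import DietSpec

#: Fluxes below this magnitude are clamped to zero in reported tables.
DISPLAY_CLAMP = 1e-9


def _clamp(x: float) -> float:
    return 0.0 if abs(x) < DISPLAY_CLAMP else x


@dataclass
class FvaResult:
    ranges: dict[str, FluxRange]
    unbounded: set[str] = field(default_factory=set)

    def __getitem__(self, rid: str) -> FluxRange:
        return self.ranges[rid]

    def __contains__(self, rid: str) -> bool:
        return rid in self.ranges

    def to_frame(self, clamp: bool = True) -> pd.DataFrame:
        f = _clamp if clamp else (lambda x: x)
        return pd.DataFrame(
            {
                "reaction": list(self.ranges),
                "minimum": [f(r.minimum) for r in self.ranges.values()],
                "maximum": [f(r.maximum) for r in self.ranges.values()],
                "unbounded": [rid in self.unbounded for rid in self.ranges],
            }
        ).set_index("reaction")


def run_fva(
    model: TaxonModel,
    reactions: Iterable[str] | None = None,
    fraction_of_optimum: float | None = None,
) -> FvaResult:
    """Min/max flux per reaction over the constrained flux polytope.

    ``reactions`` defaults to all exchange reactions.  With
    ``fraction_of_optimum`` the model's biomass objective is first
    maximized and constrained to at least that fraction of its optimum
    before ranging (the default leaves biomass free within its bounds).
    An infeasible model raises :class:`InfeasibleError` carrying the
    solver status; per-reaction unbounded optima are reported as the
    default open bound and flagged.
    """
    if reactions is None:
        reactions = [r.id for r in model.exchanges()]
    reactions = list(reactions)
    extra = None
    arrays = build_lp_arrays(model)
    if fraction_of_optimum is not None:
        from .core import LinearConstraint, fba_max

        opt = fba_max(model)
        extra = [
            LinearConstraint(
                coefficients={model.biomass_reaction_id: -1.0},
                bound=-fraction_of_optimum * opt,
                name="fraction_of_optimum",
            )
        ]
        arrays = build_lp_arrays(model, extra)

    ranges: dict[str, FluxRange] = {}
    unbounded: set[str] = set()
    n = len(arrays.reaction_ids)
    for rid in reactions:
        if rid not in arrays.index:
            raise KeyError(f"reaction {rid!r} not in model")
        j = arrays.index[rid]
        vals = []
        for sense in (1.0, -1.0):  # minimize, then maximize
            c = np.zeros(n)
            c[j] = sense
            status, fun, _ = _solve_arrays(arrays, c)
            if status == "infeasible":
                raise InfeasibleError(status, f"model infeasible while ranging {rid!r}")
            if status == "unbounded":
                unbounded.add(rid)
                vals.append(-DEFAULT_BOUND if sense == 1.0 else DEFAULT_BOUND)
            elif status == "optimal":
                vals.append(fun if sense == 1.0 else -fun)
            else:
                raise InfeasibleError(status, f"solver failure while ranging {rid!r}")
        ranges[rid] = FluxRange(minimum=vals[0], maximum=vals[1])
    return FvaResult(ranges=ranges, unbounded=unbounded)


@dataclass
class NetFluxTable:
    """Per-metabolite net secretion and net uptake, mmol/day."""

    table: pd.DataFrame  # index metabolite, columns net_secretion / net_uptake
    convention: str = "symmetric"

    def net_secretion(self, met: str) -> float:
        return float(self.table.loc[met, "net_secretion"])

    def net_uptake(self, met: str) -> float:
        return float(self.table.loc[met, "net_uptake"])

    def secreted(self, threshold: float = 0.0) -> set[str]:
        col = self.table["net_secretion"]
        return set(col.index[col > threshold])


def net_exchange_fluxes(
    fva: FvaResult, model: CommunityModel, convention: str = "symmetric"
) -> NetFluxTable:
    """Combine diet- and fecal-exchange FVA ranges into net fluxes.

    Entries exist exactly for the lumen metabolites carrying a diet or
    fecal exchange; a metabolite lacking one of the two exchanges has the
    missing term treated as 0.
    """
    if convention not in ("symmetric", "magnitude"):
        raise ValueError(f"unknown net-flux convention {convention!r}")
    rows = {}
    for base in model.lumen_bases:
        d_id = model.diet_exchange_id(base)
        f_id = model.fecal_exchange_id(base)
        d = fva.ranges.get(d_id)
        f = fva.ranges.get(f_id)
        d_min, d_max = (d.minimum, d.maximum) if d else (0.0, 0.0)
        f_min, f_max = (f.minimum, f.maximum) if f else (0.0, 0.0)
        if convention == "symmetric":
            sec = f_max + d_min
            upt = d_max + f_min
        else:  # magnitude: nonnegative capacities
            sec = max(f_max, 0.0)
            upt = max(-d_min, 0.0)
        rows[base] = {"net_secretion": _clamp(sec), "net_uptake": _clamp(upt)}
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    return NetFluxTable(table=table, convention=convention)


@dataclass
class SampleResult:
    """Results of one sample's community simulation."""

    sample_id: str
    model: CommunityModel
    fva: FvaResult
    net_fluxes: NetFluxTable
    manifest: dict

    def summary(self) -> str:
        lines = [
            f"Community simulation: sample {self.sample_id}",
            f"  members: {len(self.model.members)}  "
            f"reactions: {len(self.model.reactions)}  "
            f"metabolites: {len(self.model.metabolites)}",
            f"  diet: {self.model.diet_name}",
            f"  coupling: c={self.model.coupling_config.c}, "
            f"u={self.model.coupling_config.u}"
            if self.model.coupling_config
            else "  coupling: none",
            "",
            "  Net fluxes (mmol/day):",
            "  metabolite        net_secretion    net_uptake",
        ]
        for met, row in self.net_fluxes.table.iterrows():
            lines.append(
                f"  {met:<16} {row['net_secretion']:>14.4f} {row['net_uptake']:>13.4f}"
            )
        return "\n".join(lines)


def simulate_sample(
    models: list[TaxonModel],
    abundances: dict[str, float],
    diet: DietSpec,
    coupling: CouplingConfig | None = None,
    biomass_bounds: tuple[float, float] = (0.4, 1.0),
    sample_id: str = "sample",
    gap_fill: bool = False,
    trace_metabolites: list[str] | None = None,
    convention: str = "symmetric",
) -> SampleResult:
    """Deterministic composition of the per-sample pipeline:
    build_community -> apply_coupling -> apply_diet -> run_fva ->
    net_exchange_fluxes."""
    coupling = coupling or CouplingConfig()
    cm = build_community(
        models, abundances, coupling=coupling, biomass_bounds=biomass_bounds
    )
    cm = apply_diet(cm, diet, gap_fill=gap_fill, trace_metabolites=trace_metabolites)
    fva = run_fva(cm)
    net = net_exchange_fluxes(fva, cm, convention=convention)
    manifest = {
        "sample_id": sample_id,
        "diet": diet.name,
        "members": dict(cm.members),
        "abundances": {k: float(v) for k, v in cm.abundances.items()},
        "coupling": {"c": coupling.c, "u": coupling.u},
        "biomass_bounds": list(biomass_bounds),
        "gap_fill": gap_fill,
        "net_flux_convention": convention,
        "unresolved_diet": list(cm.unresolved_diet),
    }
    return SampleResult(
        sample_id=sample_id, model=cm, fva=fva, net_fluxes=net, manifest=manifest
    )
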