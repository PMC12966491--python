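"""Per-taxon metabolite contributions, producer and responder calls.

A taxon's contribution to a metabolite is the FVA range of its
lumen-transfer reaction for that metabolite under the full community
constraints (diet bounds, coupling, community biomass window), each
member optimized independently.  Positive flux is secretion into the
lumen, negative is uptake.

Producers: taxa whose mean secretion-side contribution (across the
cohort's samples, arithmetic mean of per-sample FVA maxima, absent
samples counting 0) reaches a threshold — default 0.01 mmol/day — for at
least one target metabolite, ranked by total mean across targets.

Responders: taxa whose mean uptake-side flux of a supplemented substrate
(mean of |per-sample FVA minima|, uptake side) reaches a threshold —
default 1 mmol/day — reported with mean, population SD and min-max.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .community import CommunityModel
from .simulation import DISPLAY_CLAMP, run_fva

PRODUCER_THRESHOLD = 0.01  # mmol/day
RESPONDER_THRESHOLD = 1.0  # mmol/day

CONTRIBUTION_COLUMNS = ["sample", "taxon", "metabolite", "minimum", "maximum"]


class ContributionError(Exception):
    pass


def compute_contributions(
    model: CommunityModel, targets: list[str], sample_id: str = "sample"
) -> pd.DataFrame:
    """FVA over every member's lumen-transfer reactions for ``targets``.

    Returns a long-format table (sample, taxon, metabolite, minimum,
    maximum).  A member without a transfer for a target contributes the
    degenerate range (0, 0); a target absent from the lumen entirely is
    skipped with a warning.
    """
    known = [t for t in targets if t in model.lumen_bases]
    missing = sorted(set(targets) - set(known))
    if missing:
        warnings.warn(
            f"targets not present in the community lumen, skipped: {missing}",
            stacklevel=2,
        )
    wanted: list[tuple[str, str, str]] = []  # (tag, base, rxn_id)
    for tag in model.members:
        for base in known:
            rid = model.transfer_id(tag, base)
            if rid in model.reactions:
                wanted.append((tag, base, rid))
    fva = run_fva(model, [rid for _, _, rid in wanted]) if wanted else None
    rows = []
    for tag in model.members:
        for base in known:
            rid = model.transfer_id(tag, base)
            if fva is not None and rid in fva:
                lo, hi = fva[rid].minimum, fva[rid].maximum
            else:
                lo = hi = 0.0
            rows.append(
                {
                    "sample": sample_id,
                    "taxon": tag,
                    "metabolite": base,
                    "minimum": 0.0 if abs(lo) < DISPLAY_CLAMP else lo,
                    "maximum": 0.0 if abs(hi) < DISPLAY_CLAMP else hi,
                }
            )
    return pd.DataFrame(rows, columns=CONTRIBUTION_COLUMNS)


def aggregate_by_rank(
    contributions: pd.DataFrame, taxonomy: pd.DataFrame, rank: str
) -> pd.DataFrame:
    """Sum contribution ranges within a taxonomic rank (interval addition)."""
    missing = sorted(set(contributions["taxon"]) - set(taxonomy.index))
    if missing:
        raise ContributionError(f"taxa missing from taxonomy table: {missing}")
    if rank not in taxonomy.columns:
        raise ContributionError(f"rank {rank!r} not in taxonomy table")
    out = contributions.copy()
    out["taxon"] = taxonomy.loc[out["taxon"], rank].values
    return (
        out.groupby(["sample", "taxon", "metabolite"], as_index=False)[
            ["minimum", "maximum"]
        ].sum()
    )


def identify_producers(
    contributions: pd.DataFrame,
    threshold: float = PRODUCER_THRESHOLD,
    targets: list[str] | None = None,
) -> pd.DataFrame:
    """Call metabolite producers from a cohort contribution table.

    The secretion-side contribution of a taxon in one sample is
    max(FVA maximum, 0).  A taxon qualifies for a metabolite when its
    mean secretion across samples is >= ``threshold``; the report is
    ranked by total mean secretion across all targets.  Wide format:
    one row per qualifying taxon, one column per metabolite plus
    ``total`` and ``metabolites`` (the set it qualifies for).
    """
    df = contributions.copy()
    if targets is not None:
        df = df[df["metabolite"].isin(targets)]
    samples = sorted(df["sample"].unique())
    df["secretion"] = df["maximum"].clip(lower=0.0)
    per_sample = (
        df.groupby(["taxon", "metabolite", "sample"])["secretion"]
        .sum()
        .unstack("sample")
        .reindex(columns=samples)
        .fillna(0.0)
    )
    mean = per_sample.mean(axis=1).unstack("metabolite", fill_value=0.0)
    qualifies = mean.ge(threshold)
    producers = mean[qualifies.any(axis=1)].copy()
    producers["total"] = producers.sum(axis=1)
    producers = producers.sort_values("total", ascending=False)
    producers["metabolites"] = [
        frozenset(qualifies.columns[qualifies.loc[t]]) for t in producers.index
    ]
    producers.attrs["threshold"] = threshold
    return producers


def producer_sets(producers: pd.DataFrame) -> dict[str, set[str]]:
    """Invert a producer report into metabolite -> set of producing taxa."""
    out: dict[str, set[str]] = {}
    for taxon, mets in producers["metabolites"].items():
        for met in mets:
            out.setdefault(met, set()).add(taxon)
    return out


def identify_responders(
    contributions: pd.DataFrame,
    substrate: str,
    threshold: float = RESPONDER_THRESHOLD,
) -> pd.DataFrame:
    """Call responders to a supplemented substrate from uptake fluxes.

    The uptake-side flux of a taxon in one sample is max(-FVA minimum, 0)
    of its transfer for the substrate.  A taxon qualifies when its mean
    uptake across samples is >= ``threshold``.  The report carries mean,
    population SD, min and max per qualifying taxon (absent taxa and
    substrate-free diets yield an empty report).  An unknown substrate —
    never a computed target — raises.
    """
    if substrate not in set(contributions["metabolite"]):
        raise ContributionError(
            f"substrate {substrate!r} is not among the computed contribution targets"
        )
    df = contributions[contributions["metabolite"] == substrate].copy()
    samples = sorted(contributions["sample"].unique())
    df["uptake"] = (-df["minimum"]).clip(lower=0.0)
    per_taxon = df.groupby(["taxon", "sample"])["uptake"].sum().unstack(fill_value=0.0)
    per_taxon = per_taxon.reindex(columns=samples, fill_value=0.0)
    report = pd.DataFrame(
        {
            "mean": per_taxon.mean(axis=1),
            "sd": per_taxon.std(axis=1, ddof=0),
            "min": per_taxon.min(axis=1),
            "max": per_taxon.max(axis=1),
        }
    )
    report["qualifies"] = report["mean"] >= threshold
    report["threshold"] = threshold
    report = report[report["qualifies"]].sort_values("mean", ascending=False)
    report.attrs["substrate"] = substrate
    return report
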