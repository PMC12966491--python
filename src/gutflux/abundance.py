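"""Coverage normalization, cutoff filtering and taxonomy aggregation.

Genome coverage (mapped reads normalized by genome size) is converted to
per-sample relative abundance; entries at or below the detection cutoff
(default a fraction of 1e-5, i.e. 0.001%) are dropped with a *strict*
comparison, and the survivors are renormalized to sum to one so that the
abundance vector can serve directly as the stoichiometric coefficients of
a community biomass reaction.  Renormalization can be disabled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: Detection cutoff as a fraction: strictly greater than 0.001% is kept.
DEFAULT_CUTOFF = 1e-5


class AbundanceError(Exception):
    pass


@dataclass
class AbundanceProfile:
    """Sample x model relative abundances after cutoff filtering.

    ``table`` has model ids as rows and samples as columns; zeros mark
    absence.  When ``renormalized`` each sample column sums to 1.
    """

    table: pd.DataFrame
    cutoff: float = DEFAULT_CUTOFF
    renormalized: bool = True

    @property
    def samples(self) -> list[str]:
        return list(self.table.columns)

    @property
    def model_ids(self) -> list[str]:
        return list(self.table.index)

    def sample_abundances(self, sample: str) -> dict[str, float]:
        """Nonzero abundances of one sample as a dict."""
        col = self.table[sample]
        return {m: float(v) for m, v in col.items() if v > 0}


def normalize_coverage(
    table: pd.DataFrame,
    cutoff: float = DEFAULT_CUTOFF,
    renormalize: bool = True,
) -> AbundanceProfile:
    """Coverage table (models x samples) -> cutoff-filtered abundances.

    Per sample: fractions = coverage / total; entries with fraction
    strictly greater than ``cutoff`` are kept (a fraction exactly equal to
    the cutoff is dropped); survivors are renormalized to sum to 1 unless
    ``renormalize=False``.  A sample with no positive coverage raises,
    naming the sample.
    """
    if (table.to_numpy() < 0).any():
        raise AbundanceError("coverage table contains negative values")
    out = {}
    for sample in table.columns:
        col = table[sample].astype(float)
        total = col.sum()
        if total <= 0:
            raise AbundanceError(f"sample {sample!r} has all-zero coverage")
        frac = col / total
        frac = frac.where(frac > cutoff, 0.0)
        if renormalize:
            kept = frac.sum()
            if kept <= 0:
                raise AbundanceError(f"sample {sample!r}: no model above cutoff {cutoff}")
            frac = frac / kept
        out[sample] = frac
    return AbundanceProfile(pd.DataFrame(out, index=table.index), cutoff, renormalize)


def shared_models(profile: AbundanceProfile, prevalence: float = 0.5) -> set[str]:
    """Models present (abundance > 0) in at least ``prevalence`` of samples."""
    if not profile.samples:
        raise AbundanceError("profile has no samples")
    present = (profile.table > 0).mean(axis=1)
    return set(present.index[present >= prevalence])


def attach_taxonomy(
    profile: AbundanceProfile, taxonomy: pd.DataFrame, rank: str
) -> pd.DataFrame:
    """Aggregate abundances at a taxonomic rank (summing within rank).

    ``taxonomy`` is indexed by model id with one column per rank; every
    model id in the profile must resolve, otherwise the unresolvable ids
    are listed in the raised error.  Per-sample totals are preserved.
    """
    missing = [m for m in profile.model_ids if m not in taxonomy.index]
    if missing:
        raise AbundanceError(f"model ids missing from taxonomy table: {missing}")
    if rank not in taxonomy.columns:
        raise AbundanceError(f"rank {rank!r} not in taxonomy table columns")
    labels = taxonomy.loc[profile.model_ids, rank]
    return profile.table.groupby(labels.values).sum()
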