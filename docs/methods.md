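# Methods

This note documents the modeling choices behind `gutflux`: the
constraint-based community model, the diet-to-flux conversion, the
decision rules for producers and responders, the synthetic study
conditions everything is validated on, and the numerical conventions.

## Units and sign conventions

Every flux in the package is **mmol/day per person**. Dietary intake is
naturally a per-day quantity, and the community biomass window (below)
is defined on the same clock, so the per-gram-dry-weight-per-hour unit
used for single-organism models is never introduced. Exchange reactions
are written `met → ∅`: positive flux exports across the system
boundary, negative flux imports. Lumen-transfer reactions are written
so that positive flux is secretion from the taxon into the lumen and
negative flux is uptake.

## Diet construction

A food-intake table (g/day per item) and a composition database
(metabolite mg per 100 g, macronutrients g per 100 g) combine to

    flux(m) = Σ_foods  intake · (mg_per_100g(m)/100) / MW(m)   [mmol/day]

Foods absent from the primary database fall back to a manually curated
secondary database; the fluxes from both sources are summed. Foods
matched by neither are excluded with a warning but retained in the
diet's provenance record, so the coverage of the conversion is always
inspectable. Missing molecular weights are an error, not a silent skip.

Energy profiling uses Atwater-style factors of 4/9/4 kcal/g for
carbohydrate/fat/protein, with 7 kcal/g for alcohol (the bundled intake
fixture includes beer); all four are configurable. The
dietary-reference (DRI) validator checks energy (default 1500–2400
kcal/day) and the three macronutrient energy shares (carbohydrate
45–65 %, fat 20–35 %, protein 10–15 %); protein additionally carries a
30 % cautionary threshold, yielding the four-way verdict
below / within / above-but-below-caution / above.

Supplement arms are plain additions on top of a base diet: doses in
grams are converted through the molecular-weight table (e.g. 5 g/day of
mannotriose at 504.44 g/mol is 9.912 mmol/day) and never mutate the
base diet object.

## Abundance profiles

Genome coverage (mapped reads normalized by genome size) is converted
per sample to relative abundance. The detection cutoff is a *strict*
comparison — fractions greater than 0.001 % (1e-5) are kept, a fraction
exactly at the cutoff is dropped — and survivors are renormalized to
sum to one, so that the abundance vector can serve directly as the
stoichiometric coefficients of the community biomass reaction. Whether
to renormalize after the cutoff is genuinely open (the filtered mass is
at most a few 0.001 %); we renormalize by default and expose
`renormalize=False`. Prevalence filters (`shared_models`) use an
inclusive `>=` floor, so "present in half the samples" qualifies at 50 %
prevalence.

## Community scaffold

Member models are namespaced with a taxon tag (`tag__` prefix on every
id). Their own exchange reactions are removed at build time — the
community scaffold is the only system boundary — and each extracellular
metabolite is linked to a shared lumen pool by one reversible transfer
reaction per taxon. Each lumen metabolite then receives exactly two
boundary reactions:

* `EX_x[d]` — diet exchange, bounds [−d(x), 0]: import-only, opened by
  `apply_diet`, closed (0, 0) for metabolites absent from the diet;
* `EX_x[fe]` — fecal exchange, bounds [0, 1e6]: export-only.

An optional gap-fill flag opens a user-listed trace set of diet
exchanges at 0.1 mmol/day for metabolites missing from the diet; the
synthetic fixtures never need it, but real reconstruction collections
usually require trace micronutrients to grow, and closing versus
trace-opening unmatched metabolites is exposed as configuration rather
than hard-coded.

The community biomass reaction consumes aₖ units of taxon k's biomass
metabolite (Σ aₖ = 1 by construction) and produces one unit of
community biomass, whose exchange is bounded to **[0.4, 1] mmol/day** —
the fecal-emptying argument: community biomass leaves the system
between once every three days and once per day. Both bounds are
overridable for sensitivity analyses.

**Coupling.** For every non-biomass reaction r of taxon k (lumen
transfers included) two inequality rows are added:

    v_r − c·v_bio,k ≤ u     and     −v_r − c·v_bio,k ≤ u

with defaults **c = 400, u = 0** — the established community-modeling
convention for the coupling factor; no experimental estimate exists for
these toys, so both are plain configuration. With u = 0, zero growth
provably collapses every flux of that member, which is verified by the
test suite as a structural property.

## FVA and net fluxes

FVA solves two independent LPs per reaction over the full constrained
polytope; by default the community biomass is *ranged* within its
[0.4, 1] window rather than fixed at an optimum (a
`fraction_of_optimum` mode exists for comparison). Net fluxes per
metabolite follow the symmetric reading of secretion/uptake accounting:

    net_secretion(m) = maxFVA(EX_m[fe]) + minFVA(EX_m[d])
    net_uptake(m)    = maxFVA(EX_m[d]) + minFVA(EX_m[fe])

with a missing exchange contributing zero. This is the only reading
that treats the two sentences symmetrically under the export-positive
convention; because the sign interpretation is genuinely ambiguous, an
alternative magnitude convention (nonnegative fecal-export and
diet-import capacities) is available via `convention="magnitude"`.
A pass-through substrate illustrates the default: with a 10 mmol/day
glucose diet and an unconstrained fermenter, maximal fecal glucose
export is 10, minimal diet flux is −10, and net secretion is exactly 0,
while a product of yield y has net secretion y·10.

## Contributions, producers, responders

A taxon's contribution to a target metabolite is the FVA range of its
lumen transfer for that metabolite under the full community constraints,
each member optimized *independently* (no joint optimality across
members is imposed — the ranges answer "how much could this taxon
secrete/consume", not "how is a particular optimum divided"). Ranges
aggregate across strains of a rank by interval addition.

* **Producers**: secretion side is max(FVA maximum, 0) per sample; the
  estimator across a cohort is the arithmetic mean over *all* samples
  (absent taxa count 0). A genus qualifies when its mean reaches
  **0.01 mmol/day** for at least one target; the report ranks genera by
  total mean across targets.
* **Responders**: uptake side is max(−FVA minimum, 0) of the
  supplemented substrate; qualification threshold **1 mmol/day**, with
  mean, population SD (ddof = 0) and min–max reported per genus. A
  substrate that is a computed target but absent from the diet yields an
  empty report (the placebo-arm control); only a substrate that was
  never computed at all raises.

Both thresholds and the mean-of-FVA-maxima estimator are configuration;
the estimator choice (versus fixed-point fluxes at one optimum) is
documented here because reported flux tables rarely state it.

## Synthetic study conditions

The generator emulates the shape of a real cohort study at toy scale:

* **Templates** — six fermenters with declared roles (see the table in
  `gutflux.synth`): acetate, propionate, butyrate (with an acetate
  cross-feeding route that *boosts* yield but is not required, so
  community behavior matches standalone capability), isobutyrate from
  valine (branched-chain amino-acid fermentation), a MOS utilizer that
  hydrolyzes mannotriose to mannose, and a low-yield generalist that
  also degrades maltodextrin. Every template draws biomass precursor
  from glucose (0.1 glucose per unit biomass) and grows on the fixture
  diet. Capabilities are *declared* in the template and independently
  verified by standalone FBA in the tests, so recovery checks are not
  circular.
* **Cohorts** — default 10 samples over the 6 templates; abundances are
  symmetric Dirichlet(α = 5.0) draws (moderately even toy communities,
  chosen once as a realistic mock-community evenness), converted to
  coverages at depth 1000 with multiplicative lognormal noise
  (log-sd 0.1). Every byte is a deterministic function of the seed.
* **Food fixture** — a verbatim 25-row transcription of a published
  national intake table (19 items matched to the primary composition
  database, 6 traditional foods of which 2 carry manual compositions),
  with synthetic plausible-magnitude compositions in which glucose
  stands in for available carbohydrate and valine for fermentable
  branched-chain amino acids. The resulting base diet supplies ~1290
  mmol/day glucose and ~41 mmol/day valine. Intervention arms follow a
  published trial design: placebo = base + 10 g/day maltodextrin,
  prebiotic = base + 5 g/day MOS + 5 g/day maltodextrin.

What the toys deliberately do **not** emulate: genome-scale reaction
counts (thousands per organism), elemental/charge balance, realistic
yields and maintenance costs, micronutrient requirements, and strain
redundancy within species. Passing the recovery tests therefore shows
the *pipeline logic* (assembly, coupling, FVA, thresholding) is sound —
not that real AGORA-scale communities would give quantitatively similar
fluxes.

## Numerics

* LP layer: `scipy.optimize.linprog` (HiGHS), dense arrays; models here
  are far below the sparse-matrix threshold.
* Feasibility/optimality tolerance 1e-6 absolute throughout; FVA
  asserts min ≤ max within the same tolerance.
* Default open bound ±1e6 mmol/day keeps every LP bounded; per-reaction
  unbounded FVA sub-problems are reported at ±1e6 with a flag rather
  than as errors.
* Reported tables clamp |v| < 1e-9 to 0 for readability; raw values are
  retained on the result objects.
* Infeasibility (e.g. a starvation diet with a positive community
  biomass floor) is surfaced as an error with solver status, never
  repaired or clamped.
* The independent reference for FVA is exhaustive vertex enumeration of
  the flux polytope projected onto the null space of S (pure linear
  algebra, no LP solver); it is combinatorial and used on networks of
  at most a dozen reactions.

## Validation problem sizes

The acceptance script runs, per invocation: 4 toy networks against the
vertex oracle (~25 reactions ranged), a 6-member coupling-collapse
community (~47 member reactions), 100 random abundance tables, 20
cohorts × 10 samples × 3 diet arms for producer/responder recovery
(200 community builds per arm), and 50 diet-bound perturbations for
monotonicity — about half a minute on one CPU. These sizes were chosen
so the whole validation remains a desk-scale computation while every
decision rule is exercised across cohort-level variation.

## JSON model dialect

`load_model`/`save_model` round-trip the following structure losslessly
(SBML L3+FBC is also read and written via cobrapy, but carries no
reaction `kind`, taxonomy, or coupling metadata):

```json
{
  "dialect_version": 1,
  "model_id": "acetogen",
  "biomass_reaction_id": "biomass",
  "taxonomy": {"phylum": "...", "family": "...", "genus": "...", "species": "..."},
  "metabolites": [
    {"id": "glc[e]", "name": "glucose", "compartment": "e",
     "molecular_weight": 180.16}
  ],
  "reactions": [
    {"id": "EX_glc", "stoichiometry": {"glc[e]": -1.0},
     "lower_bound": -1e6, "upper_bound": 1e6, "kind": "exchange"}
  ],
  "community": {
    "members": {"tag": "model_id"},
    "abundances": {"tag": 0.5},
    "member_biomass": {"tag": "tag__biomass"},
    "member_reactions": {"tag": ["tag__..."]},
    "lumen_bases": ["glc"],
    "diet_name": "average_diet",
    "coupling_config": {"c": 400.0, "u": 0.0},
    "coupling": [
      {"coefficients": {"tag__ferm": 1.0, "tag__biomass": -400.0},
       "bound": 0.0, "name": "cpl_up__tag__ferm"}
    ]
  }
}
```

Bounds absent from a file default to ±1e6; the `community` block is
present only for community models. Reaction `kind` is one of
`internal`, `transport`, `exchange`, `biomass`, `community_biomass`.

## Known limitations

* Contribution FVA bounds are *potentials*; summed member maxima can
  exceed the community-level maximum because each member is optimized
  separately (the conservation direction Σ member maxima ≥ community
  maximum is tested).
* No host compartment, no dynamic (time-course) simulation, no flux
  sampling or parsimonious FBA.
* The diet builder performs no fuzzy food matching; names must match a
  composition entry exactly or be routed through the manual database.
* Dense LP assembly caps practical community size well below real
  AGORA-scale cohorts; the architecture (explicit constraint rows over
  a reaction-id index) ports directly to a sparse backend.
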