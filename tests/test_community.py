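"""Community assembly: tagging, scaffold, coupling, diet application."""

import pytest

from gutflux.community import (
    CouplingConfig,
    apply_coupling,
    apply_diet,
    build_community,
    tag_taxon_model,
)
from gutflux.core import (
    InfeasibleError,
    Metabolite,
    ModelError,
    Reaction,
    TaxonModel,
    fba_max,
)
from gutflux.diet import DietSpec
from gutflux.simulation import run_fva


def four_reaction_taxon(model_id: str) -> TaxonModel:
    """glc[e] -> glc[c] -> 2 ac[e]; biomass from glc.  Shares the glc and
    ac lumen pools when merged."""
    m = TaxonModel(model_id=model_id)
    for mid, comp in (("glc[e]", "e"), ("glc[c]", "c"), ("ac[c]", "c"),
                      ("ac[e]", "e"), ("biomass[c]", "c")):
        m.add_metabolite(Metabolite(id=mid, compartment=comp))
    m.add_reaction(Reaction("T_glc", {"glc[e]": -1.0, "glc[c]": 1.0}, 0, 1e6, "transport"))
    m.add_reaction(Reaction("ferm", {"glc[c]": -1.0, "ac[c]": 2.0}, 0, 1e6, "internal"))
    m.add_reaction(Reaction("T_ac", {"ac[c]": -1.0, "ac[e]": 1.0}, 0, 1e6, "transport"))
    m.add_reaction(
        Reaction("biomass", {"glc[c]": -0.1, "biomass[c]": 1.0}, 0, 1e6, "biomass")
    )
    m.biomass_reaction_id = "biomass"
    return m


class TestTagging:
    def test_ids_prefixed_once_and_counts_kept(self):
        m = four_reaction_taxon("t1")
        tagged = tag_taxon_model(m, "t1")
        assert len(tagged.reactions) == 4
        assert all(rid.startswith("t1__") for rid in tagged.reactions)
        assert all(rid.count("t1__") == 1 for rid in tagged.reactions)
        # stoichiometry untouched apart from the namespace
        assert tagged.reactions["t1__ferm"].stoichiometry == {
            "t1__glc[c]": -1.0,
            "t1__ac[c]": 2.0,
        }

    def test_different_tags_give_disjoint_ids(self):
        m = four_reaction_taxon("x")
        a = tag_taxon_model(m, "a")
        b = tag_taxon_model(m, "b")
        assert set(a.reactions).isdisjoint(set(b.reactions))

    def test_duplicate_tag_rejected_at_build(self):
        a = four_reaction_taxon("same")
        b = four_reaction_taxon("same")
        with pytest.raises(ModelError, match="duplicate"):
            build_community([a, b], {"same": 1.0})

    def test_empty_tag_rejected(self):
        with pytest.raises(ModelError, match="nonempty"):
            tag_taxon_model(four_reaction_taxon("x"), "")


class TestBuildCommunity:
    def test_single_taxon_biomass_coefficient(self):
        cm = build_community([four_reaction_taxon("solo")], {"solo": 1.0})
        stoich = cm.reactions["community_biomass"].stoichiometry
        assert stoich["solo__biomass[c]"] == -1.0
        assert stoich["community_biomass[u]"] == 1.0

    def test_abundances_become_stoichiometric_coefficients(self):
        cm = build_community(
            [four_reaction_taxon("a"), four_reaction_taxon("b")], {"a": 0.7, "b": 0.3}
        )
        stoich = cm.reactions["community_biomass"].stoichiometry
        assert stoich["a__biomass[c]"] == pytest.approx(-0.7)
        assert stoich["b__biomass[c]"] == pytest.approx(-0.3)
        assert -sum(v for k, v in stoich.items() if v < 0) == pytest.approx(1.0)

    def test_reaction_count_by_construction(self):
        # 2 taxa x 4 member reactions + 2 transfers/taxon (glc, ac)
        # + 2 diet + 2 fecal exchanges + community biomass + its exchange
        cm = build_community(
            [four_reaction_taxon("a"), four_reaction_taxon("b")], {"a": 0.5, "b": 0.5}
        )
        assert len(cm.reactions) == 2 * 4 + 2 * 2 + 2 + 2 + 1 + 1
        assert sorted(cm.lumen_bases) == ["ac", "glc"]

    def test_community_biomass_bounds_default(self):
        cm = build_community([four_reaction_taxon("a")], {"a": 1.0})
        ex = cm.reactions["EX_community_biomass[fe]"]
        assert (ex.lower_bound, ex.upper_bound) == (0.4, 1.0)

    def test_scaffold_reactions_conserve_one_to_one(self):
        cm = build_community([four_reaction_taxon("a")], {"a": 1.0})
        for rid in ("IEX__a__glc", "EX_glc[d]", "EX_glc[fe]"):
            coeffs = sorted(cm.reactions[rid].stoichiometry.values())
            assert coeffs in ([-1.0], [-1.0, 1.0])

    def test_bad_abundances_rejected(self):
        a = four_reaction_taxon("a")
        with pytest.raises(ModelError, match="sum to 1"):
            build_community([a], {"a": 0.9})
        with pytest.raises(ModelError, match="match"):
            build_community([a], {"other": 1.0})
        with pytest.raises(ModelError, match="zero members"):
            build_community([], {})


class TestCoupling:
    def test_coupling_row_count(self):
        cm = build_community(
            [four_reaction_taxon("a"), four_reaction_taxon("b")], {"a": 0.5, "b": 0.5}
        )
        # per taxon: 4 member + 2 transfer reactions, minus biomass -> 5, x2 rows
        assert len(cm.coupling) == 2 * 2 * 5

    def test_flux_capped_at_c_times_biomass(self):
        # fix v_bio = 0.5 via the community biomass exchange; c=400 caps
        # every member flux at |v| <= 200.  The acetate transport is the
        # binding constraint (2 acetate per glucose), so it hits 200
        # exactly while upstream fluxes stay at half that (plus the fixed
        # biomass glucose demand 0.1 * 0.5).
        cm = build_community([four_reaction_taxon("a")], {"a": 1.0},
                             biomass_bounds=(0.5, 0.5))
        cm = apply_diet(cm, DietSpec("rich", {"glc": 1e4}))
        fva = run_fva(cm, cm.member_reactions["a"])
        assert fva["a__T_ac"].maximum == pytest.approx(200.0, abs=1e-6)
        assert fva["a__ferm"].maximum == pytest.approx(100.0, abs=1e-6)
        assert fva["a__T_glc"].maximum == pytest.approx(100.05, abs=1e-6)
        for rng in fva.ranges.values():
            assert -200.0 - 1e-6 <= rng.minimum <= rng.maximum <= 200.0 + 1e-6

    def test_slack_only_regime(self):
        # u=5 with zero growth allowed: |v| <= 5
        cm = build_community([four_reaction_taxon("a")], {"a": 1.0},
                             coupling=CouplingConfig(c=400.0, u=5.0),
                             biomass_bounds=(0.0, 0.0))
        cm = apply_diet(cm, DietSpec("rich", {"glc": 1e4}))
        fva = run_fva(cm, ["a__T_ac", "a__T_glc"])
        assert fva["a__T_ac"].maximum == pytest.approx(5.0, abs=1e-6)
        assert fva["a__T_glc"].maximum == pytest.approx(2.5, abs=1e-6)

    def test_zero_growth_collapses_member(self):
        cm = build_community(
            [four_reaction_taxon("a"), four_reaction_taxon("b")], {"a": 0.5, "b": 0.5},
            biomass_bounds=(0.0, 1.0),
        )
        cm = apply_diet(cm, DietSpec("rich", {"glc": 100.0}))
        cm.reactions[cm.member_biomass["a"]].upper_bound = 0.0
        fva = run_fva(cm, cm.member_reactions["a"])
        for r in fva.ranges.values():
            assert abs(r.minimum) <= 1e-6 and abs(r.maximum) <= 1e-6

    def test_reconfiguring_coupling_replaces_rows(self):
        cm = build_community([four_reaction_taxon("a")], {"a": 1.0})
        n = len(cm.coupling)
        apply_coupling(cm, CouplingConfig(c=100.0, u=1.0))
        assert len(cm.coupling) == n
        assert all(c.bound == 1.0 for c in cm.coupling)


class TestApplyDiet:
    def test_diet_flux_becomes_import_bound(self, sample_community):
        cm = apply_diet(sample_community, DietSpec("d", {"glc": 10.0}))
        rxn = cm.reactions[cm.diet_exchange_id("glc")]
        assert (rxn.lower_bound, rxn.upper_bound) == (-10.0, 0.0)

    def test_absent_metabolite_closed(self, sample_community):
        cm = apply_diet(sample_community, DietSpec("d", {"glc": 10.0}))
        rxn = cm.reactions[cm.diet_exchange_id("val")]
        assert (rxn.lower_bound, rxn.upper_bound) == (0.0, 0.0)

    def test_base_model_unmodified(self, sample_community):
        before = sample_community.reactions[
            sample_community.diet_exchange_id("glc")
        ].lower_bound
        apply_diet(sample_community, DietSpec("d", {"glc": 123.0}))
        assert sample_community.reactions[
            sample_community.diet_exchange_id("glc")
        ].lower_bound == before

    def test_gap_fill_opens_trace_imports(self, sample_community):
        cm = apply_diet(
            sample_community,
            DietSpec("d", {"glc": 10.0}),
            gap_fill=True,
            trace_metabolites=["val"],
        )
        assert cm.reactions[cm.diet_exchange_id("val")].lower_bound == -0.1

    def test_unresolvable_diet_entry_warns(self, sample_community):
        with pytest.warns(UserWarning, match="unobtainium"):
            cm = apply_diet(sample_community, DietSpec("d", {"glc": 1.0, "unobtainium": 2.0}))
        assert cm.unresolved_diet == ["unobtainium"]

    def test_starvation_is_infeasible_not_repaired(self):
        cm = build_community([four_reaction_taxon("a")], {"a": 1.0})
        cm = apply_diet(cm, DietSpec("empty", {}))
        with pytest.raises(InfeasibleError):
            run_fva(cm, [cm.fecal_exchange_id("ac")])


class TestSingleTaxonEquivalence:
    def test_community_reproduces_standalone_optimum(self, template_models, base_diet):
        taxon = template_models["acetogen"]
        standalone = taxon.copy()
        for rxn in standalone.exchanges():
            base = next(iter(rxn.stoichiometry)).split("[")[0]
            rxn.lower_bound = -base_diet.fluxes.get(base, 0.0)
        expected = fba_max(standalone)
        cm = build_community([taxon], {"acetogen": 1.0}, biomass_bounds=(0.0, 1e6))
        cm = apply_diet(cm, base_diet)
        fva = run_fva(cm, [cm.member_biomass["acetogen"]])
        assert fva[cm.member_biomass["acetogen"]].maximum == pytest.approx(
            expected, rel=1e-6
        )
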