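"""Per-taxon contributions, producer calls, responder calls."""

import pandas as pd
import pytest

from gutflux import synth
from gutflux.community import apply_diet, build_community
from gutflux.contributions import (
    ContributionError,
    aggregate_by_rank,
    compute_contributions,
    identify_producers,
    identify_responders,
    producer_sets,
)
from gutflux.simulation import run_fva

TARGETS = ["ac", "ppa", "but", "ibut", "mos"]


def _community(template_models, abund, diet):
    cm = build_community([template_models[m] for m in abund], abund)
    return apply_diet(cm, diet)


class TestComputeContributions:
    def test_taxon_without_pathway_contributes_nothing(
        self, template_models, base_diet
    ):
        cm = _community(
            template_models, {"acetogen": 0.5, "propionogen": 0.5}, base_diet
        )
        contrib = compute_contributions(cm, ["ac", "ppa"])
        row = contrib.set_index(["taxon", "metabolite"])
        # the propionogen has no acetate pathway at all
        assert row.loc[("propionogen", "ac"), "maximum"] == pytest.approx(0.0, abs=1e-6)
        assert row.loc[("acetogen", "ac"), "maximum"] > 0

    def test_sole_producer_matches_community_secretion(
        self, template_models, base_diet
    ):
        cm = _community(
            template_models, {"butyrogen": 0.5, "propionogen": 0.5}, base_diet
        )
        contrib = compute_contributions(cm, ["but"])
        member_max = contrib.set_index("taxon").loc["butyrogen", "maximum"]
        fecal = cm.fecal_exchange_id("but")
        community_max = run_fva(cm, [fecal])[fecal].maximum
        assert member_max == pytest.approx(community_max, rel=1e-6)

    def test_identical_producers_at_equal_abundance_tie(self, base_diet):
        a = synth.make_taxon_model("acetogen")
        b = synth.make_taxon_model("acetogen")
        b.model_id = "acetogen_twin"
        cm = _community(
            {"acetogen": a, "acetogen_twin": b},
            {"acetogen": 0.5, "acetogen_twin": 0.5},
            base_diet,
        )
        contrib = compute_contributions(cm, ["ac"]).set_index("taxon")
        assert contrib.loc["acetogen", "maximum"] == pytest.approx(
            contrib.loc["acetogen_twin", "maximum"], rel=1e-6
        )

    def test_member_secretion_maxima_dominate_community_maximum(
        self, template_models, cohort, base_diet
    ):
        profile, _ = cohort
        abund = profile.sample_abundances(profile.samples[0])
        cm = _community(template_models, abund, base_diet)
        contrib = compute_contributions(cm, ["ac"])
        total = contrib["maximum"].clip(lower=0).sum()
        fecal = cm.fecal_exchange_id("ac")
        assert total >= run_fva(cm, [fecal])[fecal].maximum - 1e-6

    def test_missing_target_skipped_with_warning(self, template_models, base_diet):
        cm = _community(template_models, {"acetogen": 1.0}, base_diet)
        with pytest.warns(UserWarning, match="unobtainium"):
            contrib = compute_contributions(cm, ["ac", "unobtainium"])
        assert set(contrib["metabolite"]) == {"ac"}


class TestProducerCalls:
    def test_threshold_above_all_means_gives_empty_set(self):
        contrib = pd.DataFrame(
            {"sample": ["s1"], "taxon": ["A"], "metabolite": ["ac"],
             "minimum": [0.0], "maximum": [0.5]}
        )
        assert identify_producers(contrib, threshold=1.0).empty

    def test_boundary_mean_equal_to_threshold_included(self):
        # present in half the samples at twice the threshold: mean == threshold
        contrib = pd.DataFrame(
            {
                "sample": ["s1", "s2"],
                "taxon": ["A", "B"],
                "metabolite": ["ac", "ac"],
                "minimum": [0.0, 0.0],
                "maximum": [0.02, 5.0],
            }
        )
        report = identify_producers(contrib, threshold=0.01)
        assert "A" in report.index

    def test_order_invariance(self, template_models, cohort, base_diet, taxonomy):
        profile, _ = cohort
        frames = []
        for s in profile.samples[:2]:
            abund = profile.sample_abundances(s)
            cm = _community(template_models, abund, base_diet)
            frames.append(compute_contributions(cm, TARGETS, sample_id=s))
        contrib = aggregate_by_rank(pd.concat(frames, ignore_index=True), taxonomy, "genus")
        shuffled = contrib.sample(frac=1.0, random_state=3).reset_index(drop=True)
        p1 = identify_producers(contrib)
        p2 = identify_producers(shuffled)
        assert producer_sets(p1) == producer_sets(p2)
        assert list(p1.index) == list(p2.index)  # ranking stable too

    def test_ranking_by_total_mean(self):
        contrib = pd.DataFrame(
            {
                "sample": ["s1"] * 3,
                "taxon": ["A", "B", "C"],
                "metabolite": ["ac"] * 3,
                "minimum": [0.0] * 3,
                "maximum": [1.0, 3.0, 2.0],
            }
        )
        assert list(identify_producers(contrib).index) == ["B", "C", "A"]


class TestResponderCalls:
    def test_sole_mos_utilizer_is_sole_responder(
        self, template_models, cohort, base_diet, food_db, taxonomy
    ):
        profile, truth = cohort
        _, prebiotic = synth.supplement_arms(base_diet, food_db)
        frames = []
        for s in profile.samples:
            abund = profile.sample_abundances(s)
            cm = _community(template_models, abund, prebiotic)
            frames.append(compute_contributions(cm, TARGETS, sample_id=s))
        contrib = aggregate_by_rank(pd.concat(frames, ignore_index=True), taxonomy, "genus")
        report = identify_responders(contrib, "mos", threshold=1.0)
        assert set(report.index) == truth.substrate_consumers["mos"]
        assert (report["mean"] >= 1.0).all()
        assert (report["sd"] >= 0).all()
        assert (report["min"] <= report["mean"]).all()
        assert (report["mean"] <= report["max"]).all()

    def test_substrate_free_diet_yields_empty_report(
        self, template_models, cohort, base_diet, food_db, taxonomy
    ):
        profile, _ = cohort
        placebo, _ = synth.supplement_arms(base_diet, food_db)
        s = profile.samples[0]
        abund = profile.sample_abundances(s)
        cm = _community(template_models, abund, placebo)
        contrib = aggregate_by_rank(
            compute_contributions(cm, TARGETS, sample_id=s), taxonomy, "genus"
        )
        assert identify_responders(contrib, "mos").empty

    def test_unknown_substrate_raises(self):
        contrib = pd.DataFrame(
            {"sample": ["s1"], "taxon": ["A"], "metabolite": ["ac"],
             "minimum": [0.0], "maximum": [1.0]}
        )
        with pytest.raises(ContributionError, match="bogus"):
            identify_responders(contrib, "bogus")

    def test_shared_pool_uptake_bounded_by_import(
        self, base_diet, food_db, taxonomy
    ):
        # two MOS utilizers: each alone may take the whole pool, but any
        # single feasible solution cannot exceed the community import bound
        a = synth.make_taxon_model("mos_utilizer")
        b = synth.make_taxon_model("mos_utilizer")
        b.model_id = "mos_utilizer_2"
        _, prebiotic = synth.supplement_arms(base_diet, food_db)
        cm = _community(
            {"mos_utilizer": a, "mos_utilizer_2": b},
            {"mos_utilizer": 0.5, "mos_utilizer_2": 0.5},
            prebiotic,
        )
        contrib = compute_contributions(cm, ["mos"]).set_index("taxon")
        mos_bound = prebiotic.fluxes["mos"]
        for t in ("mos_utilizer", "mos_utilizer_2"):
            assert -contrib.loc[t, "minimum"] <= mos_bound + 1e-6


class TestAggregateByRank:
    def test_interval_addition_within_genus(self, taxonomy):
        contrib = pd.DataFrame(
            {
                "sample": ["s1", "s1"],
                "taxon": ["strain1", "strain2"],
                "metabolite": ["ac", "ac"],
                "minimum": [-1.0, 0.0],
                "maximum": [3.0, 2.0],
            }
        )
        tax = pd.DataFrame({"genus": ["G", "G"]}, index=["strain1", "strain2"])
        agg = aggregate_by_rank(contrib, tax, "genus")
        assert agg.loc[0, "maximum"] == pytest.approx(5.0)
        assert agg.loc[0, "minimum"] == pytest.approx(-1.0)

    def test_unresolvable_taxon_raises(self):
        contrib = pd.DataFrame(
            {"sample": ["s1"], "taxon": ["mystery"], "metabolite": ["ac"],
             "minimum": [0.0], "maximum": [1.0]}
        )
        with pytest.raises(ContributionError, match="mystery"):
            aggregate_by_rank(contrib, pd.DataFrame({"genus": []}), "genus")
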