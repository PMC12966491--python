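import pytest

from gutflux import synth
from gutflux.abundance import normalize_coverage


@pytest.fixture(scope="session")
def food_db():
    return synth.make_food_db()


@pytest.fixture(scope="session")
def base_diet(food_db):
    return synth.fixture_diet(food_db)


@pytest.fixture(scope="session")
def template_models():
    return {name: synth.make_taxon_model(name) for name in synth.default_templates()}


@pytest.fixture(scope="session")
def taxonomy():
    return synth.taxonomy_table()


@pytest.fixture(scope="session")
def cohort():
    coverage, truth = synth.make_cohort(n_samples=4, seed=11)
    return normalize_coverage(coverage), truth


@pytest.fixture()
def sample_community(template_models, cohort, base_diet):
    from gutflux.community import apply_diet, build_community

    profile, _ = cohort
    abund = profile.sample_abundances(profile.samples[0])
    cm = build_community([template_models[m] for m in abund], abund)
    return apply_diet(cm, base_diet)
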