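import pytest

from spliceppi import synthetic_fixtures as sf

SCENARIOS = sorted(sf.named_scenarios())


@pytest.fixture(scope="session")
def scenario_fixtures():
    """All named scenario fixtures, built once per session."""
    return {name: fn(seed=0) for name, fn in sf.named_scenarios().items()}


@pytest.fixture(scope="session")
def scenario_pipelines(scenario_fixtures):
    """The real pipeline (store, graph, posnet) per named scenario."""
    return {name: fx.build_pipeline() for name, fx in scenario_fixtures.items()}


@pytest.fixture(scope="session")
def nck2(scenario_fixtures, scenario_pipelines):
    return scenario_fixtures["two_domain_partial_loss"], scenario_pipelines["two_domain_partial_loss"]


@pytest.fixture(scope="session")
def bag1(scenario_fixtures, scenario_pipelines):
    return scenario_fixtures["single_domain_loss"], scenario_pipelines["single_domain_loss"]


@pytest.fixture(scope="session")
def random_pipeline():
    """One seeded random fixture with structures, plus its pipeline."""
    fx = sf.random_fixture(seed=11)
    return fx, fx.build_pipeline()


def entrez_of(fixture: sf.Fixture, symbol: str) -> str:
    genes = fixture.tables["genes"]
    return genes.loc[genes["symbol"] == symbol, "entrez_id"].iloc[0]
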