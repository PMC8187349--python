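import pytest

from moanet import (
    AnnealSchedule,
    DiseaseProfile,
    DrugProfile,
    PropagationConfig,
    ScenarioConfig,
    SignedNetwork,
    SolutionModel,
    default_scenario,
    sample_ensemble,
)

#: shortened cooling schedule used by tests that only need a reasonable
#: (not maximal-quality) fit; the library default stays untouched
FAST_SCHEDULE = AnnealSchedule(t0=1.0, cooling=0.9, steps_per_temp=20, t_floor=0.01)


@pytest.fixture
def chain_network() -> SignedNetwork:
    """A -> B -> C with one activation and one inhibition."""
    return SignedNetwork.from_edges([("A", "B", 1), ("B", "C", -1)])


@pytest.fixture
def chain_model(chain_network) -> SolutionModel:
    weights = {("A", "B"): 1.0, ("B", "C"): -1.0}
    return SolutionModel(
        network=chain_network,
        weights=weights,
        config=PropagationConfig(damping=1.0),
    )


@pytest.fixture
def toy_drug() -> DrugProfile:
    return DrugProfile(name="toy-drug", targets=(("A", -1),))


@pytest.fixture
def toy_disease() -> DiseaseProfile:
    return DiseaseProfile(
        name="toy-disease",
        effectors=(("B", 1, "m1"), ("C", -1, "m2")),
    )


@pytest.fixture(scope="session")
def scenario():
    """Default planted scenario shared across scoring/MoA tests."""
    return default_scenario(seed=1)


@pytest.fixture(scope="session")
def small_ensemble(scenario):
    """A small trained ensemble on the shared scenario (fast schedule)."""
    return sample_ensemble(
        scenario.network,
        scenario.drug,
        scenario.restrictions,
        n=6,
        seed=3,
        schedule=FAST_SCHEDULE,
    )
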