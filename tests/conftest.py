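import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("det")

from mitrametab import grammar as G, network as N, synthetic as S, thermochem as T


@pytest.fixture(scope="session")
def grammar():
    return G.default_grammar()


@pytest.fixture(scope="session")
def all_codes(grammar):
    return G.enumerate_metabolites(grammar, ["M", "H"])


@pytest.fixture(scope="session")
def full_steps(grammar, all_codes):
    return N.build_network(all_codes, grammar)


@pytest.fixture(scope="session")
def clean_study():
    """Zero-noise synthetic study over the full two-parent network."""
    return S.generate_records(S.SyntheticSpec(seed=11, noise_sd=0.0))


@pytest.fixture(scope="session")
def clean_thermo(clean_study):
    return T.thermo_table(clean_study.records)
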