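import pytest

from natrofba import ExchangeSpec, ToyNetworkSpec, generate_toy_network, toy_growth_builder


@pytest.fixture
def toy_spec():
    return ToyNetworkSpec()


@pytest.fixture
def toy_net(toy_spec):
    return generate_toy_network(toy_spec)


@pytest.fixture
def toy_builder(toy_spec):
    return toy_growth_builder(toy_spec)


@pytest.fixture
def toy_exchanges():
    def make(acetate, o2):
        return ExchangeSpec(
            ubiquitous=frozenset({"co2", "h2o"}),
            parameterized={"acetate": float(acetate), "o2": float(o2)},
            secretion_only=frozenset({"biomass"}),
        )

    return make
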