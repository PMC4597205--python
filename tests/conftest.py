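import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

import booldyn as bd


@pytest.fixture(scope="session")
def cac():
    return bd.load_model("cac_synthetic")


@pytest.fixture(scope="session")
def pro_tumor():
    return bd.load_scenario("pro_tumor_dc")


@pytest.fixture(scope="session")
def reduced_cac(cac, pro_tumor):
    trace = bd.reduce_network(bd.apply_scenario(cac, pro_tumor),
                              protected={"Proliferation", "Apoptosis"})
    return trace


@pytest.fixture()
def toggle():
    return bd.make_toy("toggle")


@pytest.fixture()
def cascade():
    return bd.make_toy("cascade")
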