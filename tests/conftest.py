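import pytest

from deactkit import activation_protocol, deactivation_protocol, cohorts


@pytest.fixture(scope="session")
def deact_proto():
    return deactivation_protocol()


@pytest.fixture(scope="session")
def act_proto():
    return activation_protocol()


@pytest.fixture(scope="session")
def wt_model():
    """WT generator with default noise and between-oocyte variability."""
    return cohorts.paper_model("WT")


@pytest.fixture(scope="session")
def wt_clean():
    """WT generator stripped of noise, leak and jitter (oracle limit)."""
    return cohorts.paper_model(
        "WT", noise_sd_frac=0.0, oocyte_cv=0.0, g_leak=0.0
    )
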