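import pytest

from photophys import SimScenario, load_scenario


@pytest.fixture(scope="session")
def scenario() -> SimScenario:
    return load_scenario("cpftsy_study")


@pytest.fixture()
def noisefree(scenario) -> SimScenario:
    """A copy of the packaged scenario with every noise source switched off."""
    sc = SimScenario.from_dict(scenario.to_dict())
    sc.fluor["noise_cv"] = 0.0
    sc.rlc["noise_cv"] = 0.0
    sc.ecs["noise_sd"] = 0.0
    sc.pigments["noise_cv"] = 0.0
    sc.growth["noise_cv"] = 0.0
    sc.photoinhibition["noise_cv"] = 0.0
    return sc
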