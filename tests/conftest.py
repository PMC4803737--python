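import pytest

from wearkin import synth


@pytest.fixture(scope="session")
def clean_shoulder():
    """Noise-free bi-articular shoulder dataset under the default kinesiology split."""
    scenario = synth.ShoulderScenario(
        noise=synth.NoiseModel(orient_deg=0.0, strain_ohm=0.0, gold_m=0.0), seed=0
    )
    return synth.gen_shoulder(scenario), scenario


@pytest.fixture(scope="session")
def noisy_gold_shoulder():
    """Same conditions with 2 mm optical gold-standard noise only."""
    scenario = synth.ShoulderScenario(
        noise=synth.NoiseModel(orient_deg=0.0, strain_ohm=0.0, gold_m=0.002), seed=0
    )
    return synth.gen_shoulder(scenario), scenario
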