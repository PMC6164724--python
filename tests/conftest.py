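import dataclasses

import pytest

from qcmcoag import ResonatorParams, TraceScenario


@pytest.fixture
def resonator() -> ResonatorParams:
    return ResonatorParams()


@pytest.fixture
def scenario_factory():
    """Scenario factory: noiseless by default, overrides by field name."""

    def make(**overrides) -> TraceScenario:
        defaults = dict(noise_sd=0.0)
        defaults.update(overrides)
        return dataclasses.replace(TraceScenario(), **defaults)

    return make
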