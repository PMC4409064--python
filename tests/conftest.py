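import numpy as np
import pytest

from striatal_dtt.meanfield import EffectiveWeights, FsiDriveModel, ScenarioInput
from striatal_dtt.spiking import NetworkConfig, build_network


@pytest.fixture(scope="session")
def full_config() -> NetworkConfig:
    return NetworkConfig()


@pytest.fixture(scope="session")
def full_network(full_config):
    return build_network(full_config, seed=1000)


@pytest.fixture
def weights() -> EffectiveWeights:
    return EffectiveWeights()


@pytest.fixture
def unit_gain_fsi() -> FsiDriveModel:
    """Plain co-modulated FSI rate lam_FSI = lam_CTX (no threshold)."""
    return FsiDriveModel(mode="proportional", gain=1.0, threshold=0.0)


@pytest.fixture
def clamped_fsi_10() -> FsiDriveModel:
    return FsiDriveModel(mode="clamped", clamped_rate=10.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_weights(rng: np.random.Generator) -> EffectiveWeights:
    """Random positive magnitudes with a non-degenerate recurrent matrix."""
    while True:
        vals = rng.uniform(0.02, 0.5, size=6)
        jc1, jc2 = sorted(rng.uniform(0.5, 1.5, size=2))[::-1]
        w = EffectiveWeights(
            j11=vals[0], j12=vals[1], j21=vals[2], j22=vals[3],
            j1f=vals[4], j2f=vals[5], jc1=jc1, jc2=jc2,
            jf_sym=float(rng.uniform(0.02, 0.3)),
        )
        if abs(w.det) > 1e-4:
            return w


def scenario_input_for(
    scenario: str, rng: np.random.Generator
) -> ScenarioInput:
    return ScenarioInput(
        scenario=scenario,
        lam_ctx=float(rng.uniform(0.0, 30.0)),
        delta_ctx=float(rng.uniform(0.0, 5.0)) if "additive" in scenario else 0.0,
        fsi_drive=FsiDriveModel(mode="clamped", clamped_rate=float(rng.uniform(0, 40))),
    )
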