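import numpy as np
import pytest

from vepcal.calibrators import ScoreSet
from vepcal.evidence import build_evidence_scale
from vepcal.simulate import DistributionPair, SimulationScenario, sample_calibration_set


@pytest.fixture(scope="session")
def beta_pair():
    """Well-separated class-conditional pair: pathogenic high, benign low."""
    return DistributionPair("beta", (8.0, 2.0), "beta", (2.0, 8.0))


@pytest.fixture(scope="session")
def scale01():
    return build_evidence_scale(0.1)


@pytest.fixture(scope="session")
def balanced_unit(beta_pair):
    """n=1000 balanced calibration set drawn from the beta pair."""
    scn = SimulationScenario(beta_pair, 1000, 0.5, 0.1, seed=123)
    return sample_calibration_set(scn)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def separated_scoreset(rng):
    """Perfectly separated classes for separability sanity checks."""
    return ScoreSet(
        pathogenic_scores=rng.uniform(0.8, 1.0, 100),
        benign_scores=rng.uniform(0.0, 0.2, 100),
        unit_id="sep",
    )
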