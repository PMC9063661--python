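import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from protolie.synthetic_data import GroundTruth, gen_lie_dataset, write_fixture_bundle

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ground_truth():
    return GroundTruth(seed=2019)


@pytest.fixture(scope="session")
def dataset30(ground_truth):
    """30 synthetic complexes at the study's default conditions."""
    return gen_lie_dataset(ground_truth, 30)


@pytest.fixture(scope="session")
def paper_like_bundle(tmp_path_factory):
    """Full fixture bundle (30 ligands, 4x20 ns traces), written once."""
    out = tmp_path_factory.mktemp("fixtures") / "paper_like"
    manifest = write_fixture_bundle(out, preset="paper_like", seed=2019)
    return out, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
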