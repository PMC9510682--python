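import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cacuda.io_ct import CTVolume
from cacuda.network import Classifier, FeatureGenerator, NetConfig, build_candidate_dataset
from cacuda.phantom import PhantomParams, generate_cohort
from cacuda.uda import SourceTrainConfig, train_source_detector

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_volume(voxels, spacing=(1.0, 1.0, 1.0)):
    return CTVolume(np.asarray(voxels, dtype=np.float32), spacing)


@pytest.fixture(scope="session")
def tiny_net():
    """A minimal detector configuration for fast unit tests."""
    return NetConfig(patch_size=9, g_hidden=(16,), feature_dim=8,
                     d_widths=(8,), g_conv=(3, 3, 2))


@pytest.fixture(scope="session")
def desk_net():
    """The desk-scale configuration used by the experiment runner."""
    return NetConfig(patch_size=21, g_hidden=(48,), feature_dim=16,
                     d_widths=(32,), g_conv=(6, 5, 2))


@pytest.fixture(scope="session")
def source_cohort():
    """20 training + 4 validation non-contrast phantoms."""
    samples = generate_cohort(24, 0, PhantomParams(), seed=2024)
    return samples[:20], samples[20:]


@pytest.fixture(scope="session")
def trained_detector(source_cohort, desk_net):
    """A detector trained on the 20-phantom source cohort (shared across tests)."""
    train, _ = source_cohort
    data = build_candidate_dataset([s.volume for s in train],
                                   [s.labels for s in train],
                                   [s.threshold_hu for s in train],
                                   desk_net, max_bg_per_scan=60)
    rng = np.random.default_rng(7)
    G, C = FeatureGenerator(desk_net, rng), Classifier(desk_net, rng)
    G, C, log = train_source_detector(G, C, data,
                                      SourceTrainConfig(epochs=25, seed=7))
    return G, C, log
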