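import numpy as np
import pytest

import vrcortex as vx


@pytest.fixture(scope="session")
def demo_session():
    """A mid-sized simulated session shared by read-only tests."""
    cfg = vx.SimConfig(
        n_neurons=400, n_trials=60, stimuli=("leaf1", "circle1", "leaf2"),
        coding_regime="spatial", rp_fraction=0.15,
        selective_fraction={"V1": 0.2, "medial": 0.25,
                            "lateral": 0.2, "anterior": 0.2},
        seed=123)
    session, trials, gt = vx.simulate_session(cfg)
    mask = vx.compute_running_mask(session.speed, session.frame_times)
    return cfg, session, trials, gt, mask


@pytest.fixture(scope="session")
def demo_retino():
    """A small planted encoding-model dataset shared by retinotopy tests."""
    cfg = vx.RetinoSimConfig(n_kernels=5, n_neurons=300, n_images=400,
                             n_clusters=20, noise_scale=0.0, seed=3)
    images, responses, kernels, gt = vx.simulate_image_responses(cfg)
    return cfg, images, responses, kernels, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
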