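"""Shared fixtures: small synthetic scenes and a quickly trained toy network.

Everything is generated programmatically with fixed seeds; no data files.
"""

import numpy as np
import pytest

from boxseg.networks import build_network, default_2d_spec
from boxseg.synthetic import make_benchmark
from boxseg.trainer import TrainConfig, train

TOY_RESIZE_TARGET = 48


@pytest.fixture(scope="session")
def toy_benchmark():
    """Small seen/unseen benchmark at reduced resolution for fast tests."""
    return make_benchmark(
        ("ellipse", "lobed"), ("capsule", "bean"),
        n_train=24, n_test=8, seed=101, shape=(48, 48),
        resize_target=TOY_RESIZE_TARGET,
    )


@pytest.fixture(scope="session")
def toy_net(toy_benchmark):
    """A compact 2D network briefly trained on the toy benchmark.

    The learning rate is raised above the full-scale profile so a few
    hundred iterations suffice for a usable toy model.
    """
    net = build_network(default_2d_spec(channels=4), seed=7)
    cfg = TrainConfig(max_iterations=600, initial_lr=1e-2,
                      lr_halving_interval=300, seed=7)
    train(net, toy_benchmark.train_instances, cfg)
    return net


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
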