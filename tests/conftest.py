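import numpy as np
import pytest

from dendrocable.channels import load_channel
from dendrocable.fixtures import (
    make_ball_and_stick,
    make_hh_config,
    make_passive_config,
    make_point_neuron,
    make_toy_channels,
    make_y_tree,
)
from dendrocable.model import Model
from dendrocable.morphology import build_segments, read_swc, split_to_sections


@pytest.fixture(scope="session")
def toy_channels():
    """Parsed toy channel specs (parsing is sympy-heavy; share them)."""
    return {name: load_channel(text) for name, text in make_toy_channels().items()}


@pytest.fixture(scope="session")
def hh_point_model(toy_channels):
    """Excitable single-compartment model (toy Na + Kdr + leak)."""
    return Model(
        make_point_neuron(20.0), make_hh_config(), channels=toy_channels, nseg=1
    )


@pytest.fixture(scope="session")
def passive_point_model(toy_channels):
    """Passive single-compartment model: Rm = 10 kΩ·cm², τ = 10 ms."""
    return Model(
        make_point_neuron(20.0),
        make_passive_config(g_leak=1e-4, e_leak=-65.0),
        channels=toy_channels,
        nseg=1,
    )


@pytest.fixture()
def ball_and_stick_tree():
    pt = read_swc(make_ball_and_stick())
    return pt


@pytest.fixture()
def ball_and_stick_segments():
    pt = read_swc(make_ball_and_stick())
    return build_segments(split_to_sections(pt), nseg=5)


@pytest.fixture(scope="session")
def y_tree_model(toy_channels):
    """Passive soma + stem + two branches (for cable/reduction tests)."""
    return Model(
        make_y_tree(),
        make_passive_config(g_leak=1e-4, e_leak=-65.0, Ra=150.0),
        channels=toy_channels,
        d_lambda=0.1,
    )


def rel_err(a, b):
    return abs(a - b) / abs(b)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
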