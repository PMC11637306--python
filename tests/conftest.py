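"""Shared fixtures: small morphologies and cached simulation runs."""

import numpy as np
import pytest

from axonwave.channels import ActiveDensities, CaChannelMixture, PassiveParams
from axonwave.cable import SimConfig, Stimulus, run
from axonwave.morphology import Morphology, Node, discretize
from axonwave.synth import AxonSpec, make_axon


def peak_aligned_window(time, v, pre_ms=0.6, post_ms=1.4, dt_out=0.004):
    """Resample a trace on a grid centred on its sub-sample (parabolic) peak.

    Aligning by the integer argmax leaves up to half a sample of jitter,
    which near a 500 mV/ms upstroke is ~1 mV of spurious difference; the
    parabolic refinement removes it.
    """
    i = int(np.argmax(v))
    y0, y1, y2 = v[i - 1], v[i], v[i + 1]
    dt = time[1] - time[0]
    frac = 0.5 * (y0 - y2) / (y0 - 2 * y1 + y2)
    t_peak = time[i] + frac * dt
    grid = np.arange(-pre_ms, post_ms, dt_out)
    return np.interp(t_peak + grid, time, v)


def cylinder(length_um=100, diameter_um=1.0, spacing=1.0):
    """Straight uniform cylinder along x."""
    r = diameter_um / 2
    n = int(round(length_um / spacing))
    nodes = [Node(1, None, 0.0, 0.0, 0.0, r)]
    for i in range(1, n + 1):
        nodes.append(Node(i + 1, i, i * spacing, 0.0, 0.0, r))
    return Morphology(nodes)


@pytest.fixture(scope="session")
def cylinder_grid():
    return discretize(cylinder(100, 1.0), 1.0)


@pytest.fixture(scope="session")
def passive():
    return PassiveParams()


@pytest.fixture(scope="session")
def densities():
    return ActiveDensities()


@pytest.fixture(scope="session")
def mixture():
    return CaChannelMixture()


@pytest.fixture(scope="session")
def cylinder_ap(cylinder_grid, passive, densities):
    """Propagating AP on the uniform cylinder (default kinetics)."""
    cfg = SimConfig(dt=0.004, duration=8.0,
                    stimuli=(Stimulus("current_step", 0.0, 0.3,
                                      onset=1.0, width=0.5),),
                    settle=20.0)
    return run(cylinder_grid, passive, densities, None, cfg)


@pytest.fixture(scope="session")
def long_cylinder_grid():
    return discretize(cylinder(800, 1.0), 1.0)


@pytest.fixture(scope="session")
def long_cylinder_ap(long_cylinder_grid, passive, densities):
    cfg = SimConfig(dt=0.004, duration=12.0,
                    stimuli=(Stimulus("current_step", 0.0, 0.3,
                                      onset=1.0, width=0.5),),
                    settle=20.0)
    return run(long_cylinder_grid, passive, densities, None, cfg)


@pytest.fixture(scope="session")
def varicose_axon():
    spec = AxonSpec(seed=1)
    morph = make_axon(spec)
    return morph, discretize(morph, 1.0)


@pytest.fixture(scope="session")
def varicose_ap(varicose_axon, passive, densities, mixture):
    """Homogeneous-conductance AP with Ca recording on the seeded axon."""
    _, grid = varicose_axon
    cfg = SimConfig(dt=0.004, duration=18.0,
                    stimuli=(Stimulus("current_step", 0.0, 0.3,
                                      onset=1.0, width=0.5),),
                    settle=20.0, record_ca=True)
    return run(grid, passive, densities, mixture, cfg)
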