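"""Shared fixtures: small simulated monolayers and rendered stacks.

Session-scoped so the (comparatively expensive) simulation + rendering runs
once per test session.
"""

import numpy as np
import pytest

import nucleoflow as nf
from nucleoflow import segtrack


@pytest.fixture(scope="session")
def flocking_truth():
    cfg = nf.MonolayerConfig.flocking(n_cells=150, box_size=172, n_frames=12,
                                      seed=101)
    return nf.simulate_monolayer(cfg)


@pytest.fixture(scope="session")
def jammed_truth():
    cfg = nf.MonolayerConfig.jammed(n_cells=150, box_size=172, n_frames=12,
                                    seed=101)
    return nf.simulate_monolayer(cfg)


@pytest.fixture(scope="session")
def rendered_stack(flocking_truth):
    return nf.render_frames(flocking_truth)


@pytest.fixture(scope="session")
def segmented_tracks(rendered_stack):
    obs = segtrack.segment_stack(rendered_stack)
    tracks = segtrack.link_tracks(obs, max_displacement=8.0,
                                  pixel_size=rendered_stack.pixel_size,
                                  dt=rendered_stack.dt)
    return segtrack.apply_quality_filter(tracks)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
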