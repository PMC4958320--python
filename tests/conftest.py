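import numpy as np
import pytest

from furrownet import (SimParams, run_sim, build_hex_lattice, RenderParams)


@pytest.fixture(scope="session")
def hex1():
    return build_hex_lattice(1, 1, 6.0)


@pytest.fixture(scope="session")
def hex22():
    return build_hex_lattice(2, 2, 6.0)


@pytest.fixture(scope="session")
def render_params():
    return RenderParams()


@pytest.fixture(scope="session")
def wt_traj():
    """Full wild-type-regime run on the 3x3 lattice (shared, ~20 s)."""
    params = SimParams(k_on=0.05, k_off=0.001, n_steps=8000, seed=1)
    return run_sim(params, rows=3, cols=3, snapshot_stride=200)


@pytest.fixture(scope="session")
def dunk_traj():
    """Full dunk-regime run on the 3x3 lattice (shared, ~15 s)."""
    params = SimParams(k_on=0.003, k_off=0.001, n_steps=8000, seed=1)
    return run_sim(params, rows=3, cols=3, snapshot_stride=200)


@pytest.fixture(scope="session")
def wt_render(wt_traj, render_params):
    from furrownet import render_frames
    stack, truth = render_frames(wt_traj, render_params)
    return stack


@pytest.fixture(scope="session")
def dunk_render(dunk_traj, render_params):
    from furrownet import render_frames
    stack, truth = render_frames(dunk_traj, render_params)
    return stack
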