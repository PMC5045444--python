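"""Shared fixtures: reference optics, a full R1 design, toy grids."""

import numpy as np
import pytest

from boecyto import beam_shaping as bs


@pytest.fixture(scope="session")
def paper_optics():
    """Reference design: 3 mm / 128-zone BOE, 488 nm, f = 10 mm, 16 levels."""
    return bs.OpticalConfig()


@pytest.fixture(scope="session")
def toy_optics():
    """Small grid for fast iteration tests (32 zones, pad 2 -> 64-pt FFTs)."""
    return bs.OpticalConfig(zones_per_side=32, pad_factor=2)


@pytest.fixture(scope="session")
def r1_design(paper_optics):
    """Full R1 mask design at the reference parameters (computed once)."""
    target = bs.make_target("R1", bs.focal_grid_for(paper_optics))
    mask, focal, log = bs.gs_design(target, paper_optics, bs.GSOptions())
    return {"target": target, "mask": mask, "focal": focal, "log": log}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
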