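import numpy as np
import pytest

from octseg.phantom import (PhantomConfig, generate_boundary_surfaces,
                            ground_truth_boundaries)


@pytest.fixture
def desk_config():
    """Desk-scale phantom geometry (256 x 128, 15 slices, 6 mm coverage)."""
    return PhantomConfig()


@pytest.fixture
def noisefree_config():
    """Deterministic piecewise-constant rendering: no speckle, flecks,
    shadows, atrophy or undulation."""
    return PhantomConfig(speckle_scale=0.0, fleck_count=0, shadow_count=0,
                         atrophy_severity=0.0, undulation_amp_px=0.0)


@pytest.fixture
def tiny_config():
    """Very small geometry for fast network round-trips (64 wide, 48 deep:
    padded height 64 is divisible by 2^4)."""
    return PhantomConfig(height_px=48, width_px=64, n_slices=3,
                         axial_res_um=15.0, base_thickness_um=390.0,
                         pit_depth_um=100.0, rpe_depth_frac=0.75,
                         undulation_amp_px=0.5)


@pytest.fixture
def sample_boundaries(desk_config):
    surf = generate_boundary_surfaces(desk_config, rng_seed=42)
    return ground_truth_boundaries(surf, scan_index=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
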