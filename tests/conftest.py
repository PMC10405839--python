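"""Shared fixtures: desk-scale instrument setup and cached simulations.

Simulations are session-scoped so expensive forward models (STA blocks,
multispectral frames) are computed once and reused across test modules.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from tropus.phantoms import STUDY_GROUPS, generate_phantom
from tropus.pipeline import reconstruct_msot_section, scaled_setup
from tropus.simulate import simulate_sta


@pytest.fixture(scope="session")
def setup128():
    """Desk-scale instrument: 128-element ring, 20 MS/s, 96x96 grid."""
    return scaled_setup()


@pytest.fixture(scope="session")
def setup_small():
    """Tiny ring for cheap kinematic tests."""
    return scaled_setup(n_elements=16, grid_n=48, pixel_mm=1.0)


@pytest.fixture(scope="session")
def control_phantom(setup128):
    _, _, grid = setup128
    return generate_phantom(STUDY_GROUPS["control"], 0, seed=1, grid=grid)


@pytest.fixture(scope="session")
def control_sta(setup128, control_phantom):
    geometry, config, _ = setup128
    return simulate_sta(control_phantom, geometry, config, seed=11)


@pytest.fixture(scope="session")
def exvivo_pair_metrics(setup128):
    """Paired ex vivo control/NAFLD sections through the full MSOT chain.

    Returns (stack_control, metric_control, stack_nafld, metric_nafld,
    phantom_control, phantom_nafld); the phantoms share geometry and differ
    only by the disease lipid-contrast factor.
    """
    geometry, config, grid = setup128
    spec_c = STUDY_GROUPS["exvivo_control"]
    spec_n = replace(spec_c, lipid_contrast=1.47)
    ph_c = generate_phantom(spec_c, 0, seed=1, grid=grid)
    ph_n = generate_phantom(spec_n, 0, seed=1, grid=grid)
    stack_c, m_c = reconstruct_msot_section(ph_c, geometry, config, seed=21, n_repeats=4)
    stack_n, m_n = reconstruct_msot_section(ph_n, geometry, config, seed=22, n_repeats=4)
    return stack_c, m_c, stack_n, m_n, ph_c, ph_n


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
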