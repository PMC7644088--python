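"""Shared fixtures: one synthetic RI panel reused across the suite."""

import numpy as np
import pytest

import gxtheta as gx
from gxtheta.panels import default_panel_spec, simulate_ri_panel


@pytest.fixture(scope="session")
def ri_panel():
    """100-strain RI panel, 5 chromosomes x 80 cM x 400 SNPs, seed 1."""
    return simulate_ri_panel(default_panel_spec(100, seed=1))


@pytest.fixture(scope="session")
def ri_K(ri_panel):
    return gx.compute_grm(ri_panel.genotypes)


@pytest.fixture(scope="session")
def ri_theta(ri_panel):
    return ri_panel.theta.theta
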