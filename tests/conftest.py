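"""Shared fixtures.

The three regime simulations are expensive (minutes each), so one run per
regime is shared session-wide. They use the dye-validation drop recipe
(4 nL main drop with 1 mM of each indicator, 3 x 60 pL drops of 100 mM
CaCl2) at coarse resolution (h = 20 µm) and reduced particle counts —
means are unbiased under the particle scaling, only fluctuations grow.
"""

import pytest
from hypothesis import HealthCheck, settings

from dropmix.mixing_pipeline import MixingConfig, run_regime
from dropmix.synthetic_data import make_component_spectra

settings.register_profile(
    "suite", derandomize=True, max_examples=100,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def components():
    return make_component_spectra()


@pytest.fixture(scope="session")
def massflow_result():
    """Mass-flow collision model at the default particle scale."""
    return run_regime(MixingConfig(regime="mass_flow", seed=7))


@pytest.fixture(scope="session")
def diffusion_result():
    """Diffusion-only regime, coarse lattice, reduced particle count."""
    return run_regime(MixingConfig(regime="diffusion_only", h_um=20.0,
                                   target_particles=1e4, seed=7))


@pytest.fixture(scope="session")
def cone_result():
    """Cone-jet partial-mix regime at the same resolution and seed."""
    return run_regime(MixingConfig(regime="cone_jet", h_um=20.0,
                                   target_particles=1e4, seed=7))
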