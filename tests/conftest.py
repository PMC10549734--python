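"""Shared phantom fixtures (generated at test time, no stored data)."""

import numpy as np
import pytest

from psoct import PhantomConfig, simulate_volume
from psoct.io import BoundarySet


def small_phantom_config(**overrides):
    """A desk-scale two-layer phantom; keyword overrides tweak it."""
    base = dict(shape=(128, 32, 32), surface_depth=14.0, surface_amplitude=2.0,
                surface_corr=12.0, epidermis_thickness=22.0,
                epidermis_variation=1.5, epidermis_corr=12.0,
                dn_true=500e-6, snr_db=20.0, dop=0.95, seed=7)
    base.update(overrides)
    return PhantomConfig(**base)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Speckled but detector-noise-free, fully polarized phantom."""
    cfg = small_phantom_config(snr_db=None, dop=1.0, surface_amplitude=0.0,
                               epidermis_variation=0.0)
    vol, truth = simulate_volume(cfg)
    return cfg, vol, truth


@pytest.fixture(scope="session")
def noisy_phantom():
    cfg = small_phantom_config()
    vol, truth = simulate_volume(cfg)
    return cfg, vol, truth


def truth_boundaries(truth):
    return BoundarySet(surface=truth.surface_true, dej=truth.dej_true,
                       valid_mask=np.ones(truth.surface_true.shape, dtype=bool))
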