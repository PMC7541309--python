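from __future__ import annotations

import numpy as np
import pytest

from chromatlas.simulate import SimulationConfig, generate_world


def small_config(**overrides) -> SimulationConfig:
    """Desk-scale world: same structure, reduced counts for fast tests."""
    base = dict(
        seed=11,
        genes_per_species=100,
        housekeeping_peaks=30,
        tissue_specific_per_tissue=10,
        shared_peaks=40,
        private_housekeeping=10,
        private_distal=20,
        noise_peaks_per_library=20.0,
        fragments_per_library=2000,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_world(tmp_path_factory):
    """Default-rates small world (d=0.8, noise on, duplication 0.6)."""
    cfg = small_config()
    return generate_world(cfg, tmp_path_factory.mktemp("small_world"))


@pytest.fixture(scope="session")
def clean_world(tmp_path_factory):
    """Fully deterministic detection: d=1, no noise, no duplication."""
    cfg = small_config(seed=13, replicate_detection=1.0,
                       noise_peaks_per_library=0.0, duplication_rate=0.0)
    return generate_world(cfg, tmp_path_factory.mktemp("clean_world"))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
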