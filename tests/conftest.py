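"""Shared fixtures: small synthetic multi-study datasets."""

import numpy as np
import pandas as pd
import pytest

from eqtlrep import (
    SimulationConfig,
    make_layout,
    simulate_genotypes,
    simulate_multi_study,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        panel_sizes=(120, 60, 140),
        n_genes=80,
        n_snps_per_gene=8,
        n_confounders_per_panel=2,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    """Three small panels + truth + layout, shared across tests."""
    return simulate_multi_study(small_config)


@pytest.fixture(scope="session")
def tiny_layout():
    cfg = SimulationConfig(n_genes=6, n_snps_per_gene=5, n_chromosomes=2,
                           seed=2)
    return make_layout(cfg, seed=2)


@pytest.fixture(scope="session")
def tiny_genotypes(tiny_layout):
    return simulate_genotypes(60, tiny_layout, ld_decay=0.5,
                              frac_imputed=0.2, seed=7)
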