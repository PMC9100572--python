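import numpy as np
import pandas as pd
import pytest

from latscan.latitude import StateSpan
from latscan.panel import PanelConfig, generate_panel


@pytest.fixture(scope="session")
def illinois():
    """Illinois border latitudes used by the latitude-rescaling worked example."""
    return StateSpan("Illinois", 42.496369, 37.231888, 40.0331)


@pytest.fixture(scope="session")
def default_panel():
    """One realized default synthetic panel (264 accessions), shared read-only."""
    return generate_panel(PanelConfig(seed=11))


@pytest.fixture(scope="session")
def small_panel():
    """A fast small panel for pipeline round-trips."""
    cfg = PanelConfig(
        n_accessions=80,
        e_class_counts=(56, 12, 10, 2),
        planted_effects={"GeneA": 1.5, "GeneB": 0.0},
        n_null_genes=3,
        alignment_n_genera=40,
        alignment_length=40,
        seed=5,
    )
    return generate_panel(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def stratum_latitudes(default_panel):
    """Assigned latitudes of the default panel's e1-as/E2 analysis stratum."""
    from latscan.stratify import call_e_genotypes, stratify

    e = call_e_genotypes(default_panel.genotypes)
    subset, _, _ = stratify(default_panel.metadata, e)
    return subset["LATITUDE"].to_numpy(float)
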