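import numpy as np
import pandas as pd
import pytest

import eqtlnet as eq


@pytest.fixture
def toy_binmap():
    """4 bins on 2 chromosomes, 1-based closed physical coordinates."""
    table = pd.DataFrame(
        {
            "bin_id": ["Bin1", "Bin2", "Bin3", "Bin4"],
            "chrom": ["chr1", "chr1", "chr2", "chr2"],
            "phys_start": [1, 1001, 1, 2001],
            "phys_end": [1000, 3000, 2000, 5000],
            "genetic_pos": [0.0, 5.0, 0.0, 8.0],
        }
    )
    return eq.BinMap(table)


@pytest.fixture(scope="session")
def small_population():
    """One shared desk-scale population with a planted hotspot regulator."""
    cfg = eq.SimConfig(
        n_lines=200,
        n_chromosomes=6,
        n_bins=150,
        genome_mb=150.0,
        genome_cm=700.0,
        n_etraits=250,
        n_cis=60,
        regulators=[eq.RegulatorSpec(n_targets=150)],
        n_traits=2,
        seed=3,
    )
    binmap, G, truth, E, P = eq.simulate_population(cfg)
    return cfg, binmap, G, truth, E, P


@pytest.fixture(scope="session")
def small_catalog(small_population):
    """Classified eQTL catalog mapped from the shared population."""
    from eqtlnet.pipeline import classify_catalog

    cfg, binmap, G, truth, E, P = small_population
    catalog = eq.map_all_etraits(E, G, binmap, threshold=4.95)
    classify_catalog(catalog, E.anchors)
    return catalog
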