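import numpy as np
import pandas as pd
import pytest

import contactzone as cz


@pytest.fixture(scope="session")
def landscape():
    return cz.generate_landscape(4, seed=1)


@pytest.fixture(scope="session")
def two_catchment():
    return cz.generate_landscape(2, seed=11)


@pytest.fixture(scope="session")
def sites(landscape):
    return cz.place_sites(landscape, 60, 100.0, seed=2)


@pytest.fixture(scope="session")
def simulated(landscape, sites):
    """Moderate-size simulation shared across read-only tests."""
    return cz.simulate_markers(
        landscape, sites,
        truth_config={"deltas": [0.0, 0.0, 0.0]},
        genetics_config={"divergence": 0.3},
        n_per_site=6, seed=3)


@pytest.fixture(scope="session")
def surface(simulated, sites, landscape):
    _, _, inds, _ = simulated
    surf = cz.clusterpost.site_category_surface(
        inds, ["cluster", "haplotype", "phenotype"])
    surf["catchment"] = cz.clusterpost.assign_sites_to_catchments(
        sites, landscape, seed=9).reindex(surf.index)
    surf["catchment_excluded"] = False
    return surf


@pytest.fixture()
def toy_genotypes():
    """Two groups of 4 diploids at one locus, fixed for different alleles."""
    inds = pd.DataFrame({
        "site": ["a"] * 4 + ["b"] * 4,
        "easting": np.arange(8.0),
        "northing": np.zeros(8),
    }, index=[f"i{k}" for k in range(8)])
    alleles = np.zeros((8, 1, 2), dtype=int)
    alleles[:4] = 100
    alleles[4:] = 104
    return cz.GenotypeTable(individuals=inds, alleles=alleles, loci=["L1"])
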