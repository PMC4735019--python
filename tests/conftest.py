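import numpy as np
import pytest

import switchfit as sf
from switchfit.expression import GeneSet


@pytest.fixture(scope="session")
def nnat_cohort():
    """One seeded nnat-preset cohort at n=5000 (well-separated mixture)."""
    return sf.simulate_cohort(sf.get_preset("nnat", n=5000), seed=1)


@pytest.fixture(scope="session")
def nnat_fits(nnat_cohort):
    values = nnat_cohort["trait"].to_numpy()
    binned = sf.bin_trait(values, bin_width=1.0)
    return {
        "values": values,
        "binned": binned,
        "single": sf.fit_single_gaussian(binned),
        "double": sf.fit_double_gaussian(binned),
    }


@pytest.fixture(scope="session")
def unimodal_values():
    rng = np.random.default_rng(42)
    return rng.normal(20.0, 2.0, size=2000)


@pytest.fixture(scope="session")
def expression_experiment():
    """Marker-dominant expression cohort with known latent classes."""
    return sf.simulate_expression(sf.ExpressionScenario(seed=7))


@pytest.fixture(scope="session")
def gene_sets():
    return {
        "panel": GeneSet("IGN1", sf.IGN1_GENES, "imprinted gene network 1"),
        "housekeeping": GeneSet("HK", sf.HOUSEKEEPING_GENES, "housekeeping"),
    }
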