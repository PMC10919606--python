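import pytest

from dsrbqpcr import amplifiability_matrix, simulate_dilution_series, standard_curve_from_series
from dsrbqpcr import synthetic_assay


@pytest.fixture(scope="session")
def psets():
    return synthetic_assay.primer_sets()


@pytest.fixture(scope="session")
def panel():
    return synthetic_assay.gblock_panel()


@pytest.fixture(scope="session")
def matrix(panel, psets):
    return amplifiability_matrix(panel, psets, max_mm=1)


@pytest.fixture(scope="session")
def standard_series():
    """Default-noise 7-level x 3-replicate dilution series, fixed seed."""
    return simulate_dilution_series(replicates=3, seed=101)


@pytest.fixture(scope="session")
def standard_curve(standard_series):
    sc, table = standard_curve_from_series(standard_series)
    return sc
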