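import numpy as np
import pandas as pd
import pytest

from mmpscreen.barcodes import BarcodeCatalog
from mmpscreen.synthetic import ScreenSimConfig, make_catalog

FLANK_UP = "GATGTCCACGAGGTCTCT"
FLANK_DOWN = "CGTACGCTGCAGGTCGAC"


@pytest.fixture(scope="session")
def small_catalog() -> BarcodeCatalog:
    """Ten well-separated 20-nt barcodes."""
    cfg = ScreenSimConfig(n_strains=10, min_pairwise_hamming=5, n_hit_strains=0, seed=1)
    return make_catalog(cfg)


@pytest.fixture(scope="session")
def catalog100() -> BarcodeCatalog:
    """A 100-entry catalog for nearest-neighbour oracle checks."""
    cfg = ScreenSimConfig(n_strains=100, min_pairwise_hamming=5, n_hit_strains=0, seed=7)
    return make_catalog(cfg)


@pytest.fixture()
def tiny_catalog() -> BarcodeCatalog:
    records = pd.DataFrame({
        "strain_id": ["s1", "s2", "s3"],
        "gene": ["G1", "G2", "G3"],
        "barcode": ["ACGTACGTACGTACGTACGT",
                    "TTTTCCCCGGGGAAAATTTT",
                    "GACTGACTGACTGACTGACT"],
    })
    return BarcodeCatalog(records, FLANK_UP, FLANK_DOWN)


def embed(barcode: str, flank_up: str = FLANK_UP, flank_down: str = FLANK_DOWN,
          pad5: str = "AA", pad3: str = "TT") -> str:
    """Construct a read with the barcode between exact flanks."""
    return pad5 + flank_up + barcode + flank_down + pad3
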