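import numpy as np
import pytest

from lincsig import synthdata
from lincsig.synthdata import SimulationTruth


@pytest.fixture(scope="session")
def small_annotation():
    """12 lincRNA / 18 coding-gene catalog with designated neighbor pairs."""
    catalog, pairs = synthdata.gen_annotation(
        n_linc=12, n_coding=18,
        orientation_mix={"H2H": 0.5, "H2T": 0.25, "T2T": 0.25},
        seed=11,
    )
    return catalog, pairs


@pytest.fixture(scope="session")
def planted_cohort(small_annotation):
    """Paired FPKM cohort (20 pairs) with strong planted DE on 4 lincRNAs."""
    catalog, pairs = small_annotation
    linc_ids = [f for f, g in catalog.items() if g.biotype == "lincRNA"]
    de = {linc_ids[0]: 3.0, linc_ids[1]: -3.0, linc_ids[2]: 2.0, linc_ids[3]: -2.0}
    h2h = pairs[pairs["orientation"] == "H2H"]
    truth = SimulationTruth(
        de_log2fc=de,
        rho_pairs=list(zip(h2h["linc_id"], h2h["gene_id"])),
        neighbor_rho=0.6,
        seed=5,
    )
    matrix, sheet = synthdata.gen_fpkm_cohort(catalog, n_pairs=20, truth=truth, seed=5)
    return matrix, sheet, truth


@pytest.fixture
def rng():
    return np.random.default_rng(123)
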