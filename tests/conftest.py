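import numpy as np
import pandas as pd
import pytest

from famphase.data import Pedigree, SiteTable
from famphase.simulate import SimConfig, simulate_family


@pytest.fixture(scope="session")
def child_family():
    """Small child-reference family: 2 x 30 Mb chromosomes, 2,500 sites each."""
    cfg = SimConfig(
        chrom_lengths={"chr1": 30_000_000, "chr2": 30_000_000},
        n_sites_per_chrom=2500,
        seed=7,
    )
    return simulate_family(cfg)


@pytest.fixture(scope="session")
def gp_family():
    """Grandparent-reference family: both maternal, one paternal grandparent."""
    cfg = SimConfig(
        chrom_lengths={"chr1": 30_000_000, "chr2": 30_000_000},
        n_sites_per_chrom=2500,
        reference_mode="grandparent",
        grandparents={"maternal": 2, "paternal": 1},
        n_embryos=2,
        seed=9,
    )
    return simulate_family(cfg)


@pytest.fixture()
def toy_pedigree():
    return Pedigree(
        mother_id="mom", father_id="dad", embryos=["e1"],
        reference_mode="child", reference_child_id="kid",
    )


@pytest.fixture()
def toy_table(toy_pedigree):
    """Three hand-built autosomal sites for five samples."""
    sites = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr1"],
            "pos": [100, 2_000_000, 5_000_000],
            "ref": ["A", "C", "G"],
            "alt": ["T", "G", "A"],
            "alt_freq": [0.5, 0.3, 0.8],
        }
    )
    counts = {
        "mom": np.array([[3, 2], [4, 0], [0, 5]]),
        "dad": np.array([[5, 0], [4, 0], [3, 0]]),
        "kid": np.array([[2, 2], [3, 0], [0, 4]]),
        "e1": np.array([[1, 0], [0, 1], [0, 1]]),
    }
    return SiteTable(sites, counts)
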