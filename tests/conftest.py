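import numpy as np
import pytest

from strataphy.simulate import (
    AccessorySpec, SampleDesign, simulate_pair, simulate_sample,
)


@pytest.fixture(scope="session")
def small_pair():
    """A 50 kb two-phylotype pair with two 16S copies and backbone SNPs."""
    return simulate_pair(
        length=50_000, n_genes=30, snp_rate=0.004, rrna_copies=2, seed=11
    )


@pytest.fixture(scope="session")
def clean_pair():
    """Zero-mutation pair: genomes identical apart from the 16S markers."""
    return simulate_pair(
        length=50_000, n_genes=30, snp_rate=0.0, rrna_copies=2, seed=12
    )


@pytest.fixture(scope="session")
def accessory_pair():
    """Pair carrying a genome-B accessory gene with zone-biased carriage
    (0.8 of the anoxic population, 0.2 of the oxic) and a prophage cassette."""
    spec = [AccessorySpec(
        genome="B", length=900,
        carriage={"oxic": 0.2, "interface": 0.5, "anoxic": 0.8},
        name="accB",
    )]
    return simulate_pair(
        length=50_000, n_genes=30, snp_rate=0.002, rrna_copies=2,
        accessory_spec=spec, prophage_length=4000, seed=13,
    )


def make_sample(pair, truth, sample_id="s", zone="oxic", season="summer",
                fraction_b=0.0, depth=100.0, seed=0, **kw):
    design = SampleDesign(sample_id, zone, season, fraction_b, depth)
    return design, simulate_sample(pair, design, truth, seed=seed, **kw)


@pytest.fixture()
def rng():
    """A fresh, fixed-seed generator per test: order-independent results."""
    return np.random.default_rng(2024)
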