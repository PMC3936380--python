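import numpy as np
import pandas as pd
import pytest

from phylorefugia.seqio_haplotypes import PopulationMap
from phylorefugia.synthetic_data import SimConfig, simulate_sequences


@pytest.fixture(scope="session")
def deep_split_dataset():
    """A two-group dataset with an old split and no migration: strong
    phylogeographic structure, private haplotypes on each side."""
    cfg = SimConfig(
        n_pops=8,
        samples_per_pop=[6, 8, 5, 7, 6, 8, 5, 7],
        split_times_years=(5_000_000.0,),
        deme_sizes={"north": 10_000.0, "south": 10_000.0},
        barrier_after_pop=3,
        seed=11,
    )
    return simulate_sequences(cfg)


@pytest.fixture(scope="session")
def panmictic_dataset():
    """One deme sampled as several 'populations': no structure at all."""
    cfg = SimConfig(
        n_pops=6,
        samples_per_pop=[8, 8, 8, 8, 8, 8],
        group_of_pop={f"P{i + 1:02d}": "all" for i in range(6)},
        deme_sizes={"all": 10_000.0},
        split_times_years=(),
        seed=7,
    )
    return simulate_sequences(cfg)


@pytest.fixture
def toy_popmap():
    table = pd.DataFrame({
        "sample": ["a1", "a2", "b1", "b2"],
        "population": ["A", "A", "B", "B"],
        "group": ["G1", "G1", "G2", "G2"],
        "latitude": [0.0, 0.0, 1.0, 1.0],
        "longitude": [0.0, 0.1, 2.0, 2.1],
    })
    return PopulationMap(table)


def random_alignment(rng, n_seqs, length, n_variable):
    """Small random alignment with a fixed number of variable sites."""
    base = rng.choice(list("ACGT"), size=length)
    seqs = {}
    var_sites = rng.choice(length, size=n_variable, replace=False)
    for i in range(n_seqs):
        s = base.copy()
        for site in var_sites:
            if rng.random() < 0.5:
                s[site] = rng.choice([b for b in "ACGT" if b != base[site]])
        seqs[f"s{i}"] = "".join(s)
    return seqs
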