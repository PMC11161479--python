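import numpy as np
import pandas as pd
import pytest

from wssgwas import Pedigree, sort_pedigree
from wssgwas.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def trio():
    """Sire and dam (unrelated founders) with one offspring."""
    return sort_pedigree(Pedigree.from_records([("S", None, None), ("D", None, None), ("O", "S", "D")]))


@pytest.fixture(scope="session")
def fullsib_mating():
    """Offspring of two full sibs: F = 0.25."""
    recs = [
        ("S", None, None),
        ("D", None, None),
        ("X", "S", "D"),
        ("Y", "S", "D"),
        ("O", "X", "Y"),
    ]
    return sort_pedigree(Pedigree.from_records(recs))


def random_pedigree(n: int, seed: int, p_founder: float = 0.2) -> Pedigree:
    """Random acyclic pedigree: each animal's parents drawn from earlier animals."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        if i < 2 or rng.random() < p_founder:
            records.append((f"a{i}", None, None))
        else:
            s, d = rng.choice(i, size=2, replace=False)
            records.append((f"a{i}", f"a{s}", f"a{d}"))
    return sort_pedigree(Pedigree.from_records(records))


@pytest.fixture(scope="session")
def small_dataset():
    """Compact simulated dataset reused across module tests."""
    cfg = SimConfig(
        n_founders=60,
        n_generations=3,
        offspring_per_mating=3,
        n_snps=400,
        n_chromosomes=3,
        chrom_length_bp=50_000_000,
        genotyped_fraction_last_gen=0.8,
        seed=123,
    )
    return simulate_dataset(cfg)
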