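import numpy as np
import pandas as pd
import pytest

from layersel import simdata
from layersel.config import SimConfig
from layersel.simdata import Pedigree


@pytest.fixture(scope="session")
def tiny_cfg() -> SimConfig:
    return SimConfig(
        n_generations=2,
        n_sires_per_gen=20,
        dams_per_sire=3,
        daughters_per_dam=5,
        n_snps=60,
        prop_sires_genotyped=1.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_pop(tiny_cfg):
    ped = simdata.simulate_pedigree(tiny_cfg)
    geno = simdata.simulate_genotypes(ped, tiny_cfg)
    phenos = simdata.simulate_survival(ped, tiny_cfg)
    return ped, geno, phenos


def make_pedigree(rows) -> Pedigree:
    """Build a Pedigree from (animal, sire, dam) or 5-tuples."""
    full = []
    for r in rows:
        if len(r) == 3:
            a, s, d = r
            full.append((a, s, d, 1 if s == 0 and d == 0 else 2, "M"))
        else:
            full.append(tuple(r))
    return Pedigree(
        pd.DataFrame(full, columns=["animal", "sire", "dam", "generation", "sex"])
    )


def kinship_oracle(pedigree: Pedigree) -> np.ndarray:
    """Additive relationships by recursive coancestry (independent of the
    tabular method used in the package)."""
    sire, dam = pedigree.parent_arrays()
    n = pedigree.n
    memo = {}

    def f(a, b):
        if a < 0 or b < 0:
            return 0.0
        key = (a, b) if a <= b else (b, a)
        if key in memo:
            return memo[key]
        if a == b:
            val = 0.5 * (1.0 + f(sire[a], dam[a]))
        else:
            hi, lo = (a, b) if a > b else (b, a)
            val = 0.5 * (f(lo, sire[hi]) + f(lo, dam[hi]))
        memo[key] = val
        return val

    return np.array([[2.0 * f(i, j) for j in range(n)] for i in range(n)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
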