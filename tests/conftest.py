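import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from admixchron.io import GenotypeDataset
from admixchron.simulate import SimConfig, simulate_cohort

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort():
    """Mid-size admixed cohort shared by the statistics tests.

    22 chromosomes x 2000 SNPs, truth: alpha_auto=0.40, alpha_X=0.30, n=30.
    """
    return simulate_cohort(SimConfig(seed=3))


@pytest.fixture(scope="session")
def autosomal(cohort):
    ds, _ = cohort
    return ds.restrict(chromosome_class="autosomes")


@pytest.fixture()
def tiny_ds():
    """Hand-written 4-variant, 3-sample pseudo-haploid dataset."""
    variants = pd.DataFrame(
        {
            "id": ["s1", "s2", "s3", "s4"],
            "chrom": ["1", "1", "2", "X"],
            "gpos": [0.01, 0.02, 0.005, 0.03],
            "pos": [100, 200, 50, 300],
            "ref": ["A", "A", "C", "G"],
            "alt": ["C", "G", "T", "A"],
        }
    )
    samples = pd.DataFrame(
        {
            "id": ["i1", "i2", "i3"],
            "sex": ["M", "F", "M"],
            "population": ["P1", "P1", "P2"],
        }
    )
    calls = np.array(
        [[0, 2, 2], [2, -1, 0], [0, 0, 2], [2, 0, -1]], dtype=np.int8
    )
    return GenotypeDataset(variants, samples, calls, pseudo_haploid=True)


def random_dataset(rng, n_variants=60, n_samples=8, n_pops=4, missing=0.1,
                   pseudo_haploid=True):
    """Small random dataset for oracle comparisons."""
    chroms = np.sort(rng.integers(1, 4, n_variants)).astype(str)
    gpos, pos = [], []
    for c in np.unique(chroms):
        k = (chroms == c).sum()
        g = np.sort(rng.uniform(0, 1.0, k))
        gpos.extend(g)
        pos.extend(np.arange(k) * 1000 + 1)
    variants = pd.DataFrame(
        {
            "id": [f"v{i}" for i in range(n_variants)],
            "chrom": chroms, "gpos": gpos, "pos": pos,
            "ref": "A", "alt": "C",
        }
    )
    pops = [f"pop{i % n_pops}" for i in range(n_samples)]
    samples = pd.DataFrame(
        {
            "id": [f"s{i}" for i in range(n_samples)],
            "sex": ["M" if i % 2 else "F" for i in range(n_samples)],
            "population": pops,
        }
    )
    if pseudo_haploid:
        calls = rng.choice([0, 2], size=(n_variants, n_samples)).astype(np.int8)
    else:
        calls = rng.integers(0, 3, size=(n_variants, n_samples)).astype(np.int8)
    calls[rng.random(calls.shape) < missing] = -1
    # keep male X haploid
    on_x = (variants["chrom"] == "X").to_numpy()
    male = (samples["sex"] == "M").to_numpy()
    if on_x.any():
        sub = calls[np.ix_(on_x, male)]
        sub[sub == 1] = 2
        calls[np.ix_(on_x, male)] = sub
    return GenotypeDataset(variants, samples, calls, pseudo_haploid=pseudo_haploid)
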