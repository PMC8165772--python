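"""Shared fixtures: handcrafted genotype matrices and small simulated panels."""
from __future__ import annotations

import numpy as np
import pytest

from ducksweep import (
    CoalescentParams,
    GenotypeMatrix,
    PopulationMap,
    population_allele_counts,
    simulate_genotype_matrix,
)


def make_gm(pos, dosages, samples=None, chrom="chr1", **kwargs) -> GenotypeMatrix:
    """Genotype matrix from plain lists; dosages is (n_sites, n_samples)."""
    dosages = np.asarray(dosages, dtype=np.int8)
    if samples is None:
        samples = [f"s{i + 1}" for i in range(dosages.shape[1])]
    return GenotypeMatrix.from_arrays(chrom, pos, dosages, samples, **kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def two_pop_random_gm(rng):
    """Random 40-site, 8-sample matrix with missingness, split into two populations."""
    n_sites, n_samples = 40, 8
    d = rng.integers(0, 3, size=(n_sites, n_samples)).astype(np.int8)
    d[rng.random(size=d.shape) < 0.1] = -1
    pos = np.sort(rng.choice(np.arange(1, 100_000), size=n_sites, replace=False))
    gm = make_gm(pos, d, chrom_lengths={"chr1": 100_000})
    popmap = PopulationMap(
        {s: ("A" if i < 4 else "B") for i, s in enumerate(gm.samples)}
    )
    return gm, popmap


@pytest.fixture(scope="session")
def neutral_panel():
    """Single-deme neutral panel: 10 diploids, 50 x 40-kb loci at theta = 5e-4/bp."""
    params = CoalescentParams(
        ne=78_125.0,
        samples_per_pop=(10,),
        model="single_deme",
        chrom_length=50 * 40_000,
        seed=101,
    )
    gm, popmap, truth, _ = simulate_genotype_matrix(params)
    return params, gm, popmap, truth


@pytest.fixture(scope="session")
def split_panel():
    """Two-deme clean-split panel (wild/domestic) on 60 x 40-kb loci."""
    params = CoalescentParams(
        ne=78_125.0,
        samples_per_pop=(10, 10),
        model="split",
        chrom_length=60 * 40_000,
        seed=202,
    )
    gm, popmap, truth, _ = simulate_genotype_matrix(params)
    counts = population_allele_counts(gm, popmap)
    return params, gm, popmap, counts
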