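import itertools

import numpy as np
import pandas as pd
import pytest

from piaoscan.genoscan import MISSING, GenotypeMatrix


def make_matrix(genotypes, positions=None, n_case=None, chrom="chr1",
                site_type="SNP"):
    """Build a GenotypeMatrix from a raw code array (sites × individuals)."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_ind = genotypes.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    if n_case is None:
        n_case = n_ind // 2
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.asarray(positions, dtype=np.int64),
            "ref": "A",
            "alt": "T",
            "site_type": site_type,
        }
    )
    panel = pd.DataFrame(
        {"population": ["case"] * n_case + ["control"] * (n_ind - n_case)},
        index=pd.Index([f"S{i}" for i in range(n_ind)], name="sample_id"),
    )
    return GenotypeMatrix(sites, genotypes, panel)


def random_matrix(rng, n_sites=30, n_case=5, n_control=5, missing_rate=0.0,
                  positions=None):
    geno = rng.integers(0, 3, size=(n_sites, n_case + n_control)).astype(np.int8)
    if missing_rate:
        geno[rng.random(geno.shape) < missing_rate] = MISSING
    return make_matrix(geno, positions=positions, n_case=n_case)


def pairwise_pi_site(alleles):
    """Mean pairwise differences over all allele pairs, by enumeration."""
    pairs = list(itertools.combinations(alleles, 2))
    if not pairs:
        return 0.0
    return sum(a != b for a, b in pairs) / len(pairs)


def window_pi_bruteforce(matrix, population, window=40_000, step=20_000):
    """Σ over in-window sites of exhaustive mean pairwise differences."""
    cols = matrix.population_columns(population)
    sums = {}
    for row in range(matrix.n_sites):
        chrom = matrix.sites.at[row, "chrom"]
        p0 = int(matrix.sites.at[row, "pos"]) - 1
        alleles = []
        for c in cols:
            g = int(matrix.genotypes[row, c])
            if g != MISSING:
                alleles += [1] * g + [0] * (2 - g)
        if len(alleles) < 2:
            continue
        pi = pairwise_pi_site(alleles)
        for start in range(max(0, (p0 - window) // step * step),
                           p0 + 1, step):
            if start <= p0 < start + window:
                sums[(chrom, start)] = sums.get((chrom, start), 0.0) + pi
    return sums


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
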