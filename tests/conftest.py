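import numpy as np
import pytest

from sdscreen.io_formats import FEMALE, MALE, GenotypeMatrix, Locus, SexMap


def make_matrix(geno_rows, positions=None, chrom="chr1", qual=60.0):
    """GenotypeMatrix from a list of per-sample genotype rows."""
    geno = np.asarray(geno_rows, dtype=np.int8)
    n_samples, n_loci = geno.shape
    if positions is None:
        positions = [100 * (j + 1) for j in range(n_loci)]
    loci = [Locus(chrom, int(p), "A", "C", qual) for p in positions]
    samples = [f"s{i}" for i in range(n_samples)]
    return GenotypeMatrix(samples, loci, geno)


def balanced_sexmap(n_males, n_females):
    """Sex map for make_matrix sample ids: first n_males male, rest female."""
    mapping = {f"s{i}": MALE for i in range(n_males)}
    mapping.update({f"s{i + n_males}": FEMALE for i in range(n_females)})
    return SexMap(mapping)


def sd_locus_matrix(n_males, n_females):
    """One fully sex-linked locus: males het, females hom-ref."""
    rows = [[1]] * n_males + [[0]] * n_females
    return make_matrix(rows), balanced_sexmap(n_males, n_females)


@pytest.fixture
def ten_sample_sd():
    """The paper-scale discovery design: 5 males het, 5 females hom-ref."""
    return sd_locus_matrix(5, 5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_genotype_config(rng, n_loci=1, max_per_sex=20, missing_rate=0.0):
    """Random GenotypeMatrix + SexMap with 2..max_per_sex samples per sex."""
    n_m = int(rng.integers(2, max_per_sex + 1))
    n_f = int(rng.integers(2, max_per_sex + 1))
    geno = rng.integers(0, 3, size=(n_m + n_f, n_loci)).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random(geno.shape) < missing_rate
        geno[mask] = -1
    return make_matrix(geno), balanced_sexmap(n_m, n_f), n_m, n_f
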