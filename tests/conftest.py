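import numpy as np
import pytest

from msatld.genodata import GenotypeDataset, Population


def random_dataset(
    seed: int,
    n_pops: int = 2,
    n_ind: int = 8,
    n_loci: int = 5,
    n_alleles: int = 4,
    missing_rate: float = 0.1,
    motif: int = 4,
) -> GenotypeDataset:
    """Random multiallelic dataset on a shared 4-bp allele lattice."""
    rng = np.random.default_rng(seed)
    pool = (100 + motif * np.arange(1, n_alleles + 1)).astype(np.int32)
    habitats = ["marine", "lake", "pond", "river"]
    pops = []
    for p in range(n_pops):
        geno = rng.choice(pool, size=(n_ind, n_loci, 2)).astype(np.int32)
        if missing_rate:
            miss = rng.random((n_ind, n_loci)) < missing_rate
            geno[miss] = 0
        pops.append(
            Population(f"pop{p}", habitats[p % 4], False, geno, [])
        )
    ds = GenotypeDataset(
        [f"L{i:02d}" for i in range(n_loci)], pops,
        motif_bp=np.full(n_loci, motif),
    )
    ds.validate()
    return ds


def dataset_from_genotypes(genotypes, name="p1", habitat="marine", motif=4):
    """Dataset with a single population from an (n, L, 2) allele-code array."""
    geno = np.asarray(genotypes, dtype=np.int32)
    n_loci = geno.shape[1]
    pop = Population(name, habitat, False, geno, [])
    return GenotypeDataset(
        [f"L{i:02d}" for i in range(n_loci)], [pop],
        motif_bp=np.full(n_loci, motif),
    )


@pytest.fixture
def make_random_dataset():
    return random_dataset


@pytest.fixture
def make_single_pop():
    return dataset_from_genotypes
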