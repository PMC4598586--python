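import numpy as np
import pytest

from mrrbs.genome import ReferenceSet
from mrrbs.simulate import (GenomeSpec, MethylationModel, ReadSimParams,
                            generate_genome, generate_methylome)


@pytest.fixture(scope="session")
def small_spec() -> GenomeSpec:
    return GenomeSpec(n_chromosomes=1, chrom_length=300_000, n_genes=30,
                      n_tes=45, n_tandem_repeats=5, n_inverted_repeats=4, seed=11)


@pytest.fixture(scope="session")
def small_genome(small_spec):
    return generate_genome(small_spec)


@pytest.fixture(scope="session")
def small_truth(small_genome):
    ref, ann = small_genome
    return generate_methylome(ref, ann, MethylationModel.component_default(), seed=12)


@pytest.fixture(scope="session")
def clean_sim_params() -> ReadSimParams:
    """Error-free sequencing with uniform high qualities."""
    return ReadSimParams(sequencing_error_rate=0.0, degraded_fraction=0.0,
                         quality_sd=0.0, seed=13)


def random_reference(seed: int, length: int, gc: float = 0.45,
                     name: str = "chr1") -> ReferenceSet:
    rng = np.random.default_rng(seed)
    bases = rng.choice(list("ACGT"), size=length,
                       p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return ReferenceSet({name: "".join(bases)})
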