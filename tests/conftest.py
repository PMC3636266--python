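import numpy as np
import pytest

from satchip import synthetic as sy


def random_monomer(seed: int, length: int = 234, at: float = 0.68) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"),
                              p=[at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
                   for _ in range(length))


@pytest.fixture(scope="session")
def satellite_genome():
    """500-kb single chromosome with one satellite array at genomic
    fraction 0.05 (234-bp monomer x 107 copies, 5% divergence)."""
    monomer = random_monomer(101)
    array_len = 234 * 107
    spec = sy.GenomeSpec(
        {"chr1": array_len * 20},  # fraction exactly 0.05
        repeats=(sy.RepeatArraySpec("chr1", 400000, monomer, 107, 0.05,
                                    "satMajor"),),
    )
    genome, annotation = sy.build_genome(spec, seed=101)
    return spec, genome, annotation


@pytest.fixture(scope="session")
def gene_genome():
    """2-Mb chromosome with 400 2-kb genes (5-kb spacing, alternating
    strands, lognormal expression) for metagene/ordering checks."""
    rng = np.random.default_rng(202)
    expr = rng.lognormal(mean=2.0, sigma=1.5, size=400)
    genes = []
    for i in range(400):
        start = 10000 + i * 4900
        genes.append(sy.GeneSpec(f"g{i:03d}", "chr1", start, start + 2000,
                                 "+" if i % 2 == 0 else "-",
                                 float(np.round(expr[i], 3))))
    spec = sy.GenomeSpec({"chr1": 2_000_000}, genes=tuple(genes))
    genome, annotation = sy.build_genome(spec, seed=202)
    return spec, genome, annotation
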