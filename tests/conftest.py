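import pytest

from fragbench import (
    Fragment,
    GenomeSimConfig,
    build_benchmark,
    generate_genomes,
)


@pytest.fixture(scope="session")
def genomes():
    """Three small annotated genomes with clearly biased gene codon usage."""
    config = GenomeSimConfig(
        n_genomes=3,
        genome_length=40_000,
        gene_length=(900.0, 360, 2400),
        intergenic_length=(400.0, 160, 1200),
        gc=0.5,
        codon_bias_strength=0.8,
        seed=11,
    )
    return generate_genomes(config)


@pytest.fixture(scope="session")
def bench(genomes):
    """A small stratified benchmark: 2 read lengths x 4 types x 50 reads."""
    return build_benchmark(genomes, [100, 300], n_per_type=50, seed=13)


def make_balanced_truth(n: int, read_length: int = 300) -> list[Fragment]:
    """n reads, half coding (type B) and half non-coding (type D)."""
    seq = "A" * read_length
    frags = []
    for i in range(n // 2):
        frags.append(
            Fragment(
                read_id=f"coding_{i}",
                sequence=seq,
                ftype="B",
                read_length=read_length,
                truth_interval=(0, read_length),
                genome_id="toy",
                genome_start=0,
                genome_end=read_length,
                strand="+",
                source_gene=(0, read_length),
            )
        )
        frags.append(
            Fragment(
                read_id=f"noncoding_{i}",
                sequence=seq,
                ftype="D",
                read_length=read_length,
                truth_interval=None,
                genome_id="toy",
                genome_start=0,
                genome_end=read_length,
                strand="+",
                source_gene=None,
            )
        )
    return frags
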