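"""The canonical benchmark design and the default synthetic genome set.

One benchmark sample covers seven read lengths (100-700 bp in 100 bp
steps) with 1000 reads of each of the four fragment types per length —
28,000 reads per sample, three quarters of which carry coding sequence.
The default genome set is sized so every (read length, type) stratum has
enough candidates for without-replacement sampling at that design: 20
genomes of 110 kb with ~900 bp genes separated by ~800 bp intergenic
stretches (long enough for fully intergenic 700 bp windows), GC 0.5 and
a moderately biased gene codon usage.
"""

from __future__ import annotations

from fragbench.syngen import GenomeSimConfig

READ_LENGTHS: tuple[int, ...] = (100, 200, 300, 400, 500, 600, 700)
N_PER_TYPE: int = 1000
N_REPLICATES: int = 2


def default_genome_config(seed: int = 0) -> GenomeSimConfig:
    """The default synthetic genome set backing the full benchmark design."""
    return GenomeSimConfig(
        n_genomes=20,
        genome_length=110_000,
        gene_length=(900.0, 360, 2400),
        intergenic_length=(800.0, 400, 2400),
        gc=0.5,
        codon_bias_strength=0.6,
        seed=seed,
    )
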