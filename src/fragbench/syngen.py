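"""Synthetic annotated genomes and genome I/O.

Generates bacterial-style genomes as alternating intergenic stretches
(independent bases at a target GC) and planted protein-coding genes (drawn
codon by codon from a codon-usage table that diverges from the background
by a tunable amount), with the true gene intervals recorded.  Also reads
and writes real genomes as FASTA + GFF3 so downstream stages work on
either source.

Internal coordinates are 0-based half-open throughout; GFF3 files use the
standard 1-based inclusive convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import gffutils
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from fragbench import codons
from fragbench.errors import ConfigurationError, FormatError

GFF_SOURCE = "syngen"


@dataclass(frozen=True)
class AnnotatedGenome:
    """A nucleotide sequence plus ground-truth gene intervals.

    genes are (start, end, strand) tuples in 0-based half-open genome
    coordinates, non-overlapping and sorted by start; every base outside
    a gene interval is intergenic.
    """

    id: str
    sequence: str
    genes: tuple[tuple[int, int, str], ...]

    def __post_init__(self):
        n = len(self.sequence)
        prev_end = 0
        for start, end, strand in self.genes:
            if not (0 <= start < end <= n):
                raise ValueError(
                    f"gene ({start}, {end}) outside sequence of length {n}"
                )
            if strand not in ("+", "-"):
                raise ValueError(f"bad strand {strand!r}")
            if start < prev_end:
                raise ValueError("gene intervals overlap or are unsorted")
            prev_end = end

    @property
    def gc_content(self) -> float:
        s = self.sequence
        return (s.count("G") + s.count("C")) / len(s) if s else 0.0

    def coding_mask(self) -> np.ndarray:
        """Boolean per-base mask, True where the base lies inside a gene."""
        mask = np.zeros(len(self.sequence), dtype=bool)
        for start, end, _ in self.genes:
            mask[start:end] = True
        return mask


@dataclass(frozen=True)
class GenomeSimConfig:
    """Parameters of the synthetic genome generator.

    Length distributions are (mean, min, max) in bp; gene lengths are
    rounded to multiples of 3 and include the start and stop codons.
    codon_bias_strength in [0, 1] mixes the background at-GC codon table
    (0) with a fixed biased codon-usage table (1).
    """

    n_genomes: int = 1
    genome_length: int = 100_000
    gene_length: tuple[float, int, int] = (900.0, 360, 2400)
    intergenic_length: tuple[float, int, int] = (800.0, 400, 2400)
    gc: float = 0.5
    codon_bias_strength: float = 0.6
    both_strands: bool = False
    seed: int = 0

    def validate(self) -> None:
        mean_g, min_g, max_g = self.gene_length
        mean_i, min_i, max_i = self.intergenic_length
        if self.n_genomes < 1 or self.genome_length < 100:
            raise ConfigurationError("need n_genomes >= 1 and genome_length >= 100")
        if min_g < 9 or max_g < min_g or mean_g <= 0:
            raise ConfigurationError(
                f"degenerate gene length distribution {self.gene_length}; "
                "need max >= min >= 9 (start codon + one codon + stop codon)"
            )
        if min_i < 1 or max_i < min_i or mean_i <= 0:
            raise ConfigurationError(
                f"degenerate intergenic length distribution {self.intergenic_length}"
            )
        if not 0.0 < self.gc < 1.0:
            raise ConfigurationError(f"gc must be in (0, 1), got {self.gc}")
        if self.codon_bias_strength < 0:
            raise ConfigurationError("codon_bias_strength must be >= 0")


def _draw_length(rng: np.random.Generator, dist: tuple[float, int, int]) -> int:
    mean, lo, hi = dist
    x = rng.normal(mean, mean / 4.0)
    return int(np.clip(round(x), lo, hi))


def _intergenic(rng: np.random.Generator, n: int, gc: float) -> str:
    p = codons.mononucleotide_probs(gc)
    idx = rng.choice(4, size=n, p=p)
    return "".join(codons.BASES[i] for i in idx)


def _gene(rng: np.random.Generator, n: int, gc: float, bias: float) -> str:
    # n is a multiple of 3, >= 9: ATG + body codons + stop
    body_p = codons.gene_body_codon_probs(gc, bias)
    n_body = n // 3 - 2
    body_idx = rng.choice(len(codons.SENSE_CODONS), size=n_body, p=body_p)
    stop = rng.choice(3, p=codons.stop_codon_probs(gc))
    return (
        codons.START_CODON
        + "".join(codons.SENSE_CODONS[i] for i in body_idx)
        + codons.STOP_CODONS[stop]
    )


def generate_genome(
    config: GenomeSimConfig, *, rng: np.random.Generator | None = None, index: int = 0
) -> AnnotatedGenome:
    """Generate one annotated genome deterministically from the config seed.

    The genome alternates intergenic stretches and planted genes, starts
    and ends intergenic, and records the truth intervals of every gene.
    With both_strands=True each gene's strand is chosen uniformly and the
    genomic sequence carries the reverse complement of the drawn coding
    sequence; the default plants all genes on the forward strand.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed).spawn(config.n_genomes)[index]
        )
    parts: list[str] = []
    genes: list[tuple[int, int, str]] = []
    pos = 0
    L = config.genome_length
    while True:
        gap = _draw_length(rng, config.intergenic_length)
        glen = _draw_length(rng, config.gene_length)
        glen -= glen % 3
        if pos + gap + glen > L:  # no room for another gene: pad and stop
            parts.append(_intergenic(rng, L - pos, config.gc))
            break
        parts.append(_intergenic(rng, gap, config.gc))
        pos += gap
        cds = _gene(rng, glen, config.gc, config.codon_bias_strength)
        strand = "+"
        if config.both_strands and rng.random() < 0.5:
            strand = "-"
            cds = str(Seq(cds).reverse_complement())
        parts.append(cds)
        genes.append((pos, pos + glen, strand))
        pos += glen
    return AnnotatedGenome(
        id=f"synthetic_{config.seed}_{index}",
        sequence="".join(parts),
        genes=tuple(genes),
    )


def generate_genomes(config: GenomeSimConfig) -> list[AnnotatedGenome]:
    """Generate config.n_genomes genomes from independently spawned streams."""
    config.validate()
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_genomes)
    return [
        generate_genome(config, rng=np.random.default_rng(s), index=i)
        for i, s in enumerate(seeds)
    ]


def write_genome(genome: AnnotatedGenome, fasta_path, gff3_path) -> None:
    """Write a genome as FASTA plus a GFF3 of its gene annotations."""
    record = SeqRecord(Seq(genome.sequence), id=genome.id, description="")
    SeqIO.write([record], str(fasta_path), "fasta")
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {len(genome.sequence)}\n")
        for i, (start, end, strand) in enumerate(genome.genes):
            cols = [
                genome.id,
                GFF_SOURCE,
                "gene",
                str(start + 1),  # GFF3 is 1-based inclusive
                str(end),
                ".",
                strand,
                ".",
                f"ID=gene_{i:05d}",
            ]
            fh.write("\t".join(cols) + "\n")


def read_genome(fasta_path, gff3_path) -> AnnotatedGenome:
    """Read a FASTA + GFF3 pair into an AnnotatedGenome.

    Features of type "gene" or "CDS" become truth intervals.  A feature
    extending beyond the sequence raises FormatError naming the feature.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise FormatError(
            f"{fasta_path}: expected exactly one sequence, found {len(records)}"
        )
    record = records[0]
    n = len(record.seq)
    db = gffutils.create_db(
        str(gff3_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes = []
    for ftype in ("gene", "CDS"):
        for feat in db.features_of_type(ftype):
            if feat.seqid != record.id:
                raise FormatError(
                    f"{gff3_path}: feature {feat.id} on {feat.seqid} does not "
                    f"match sequence {record.id}"
                )
            if feat.start < 1 or feat.end > n:
                raise FormatError(
                    f"{gff3_path}: feature {feat.id} ({feat.start}-{feat.end}) "
                    f"outside sequence of length {n}"
                )
            genes.append((feat.start - 1, feat.end, feat.strand or "+"))
    genes = sorted(set(genes))
    return AnnotatedGenome(id=record.id, sequence=str(record.seq).upper(), genes=tuple(genes))
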