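"""Simulation of the four ground-truthed fragment types.

From an annotated genome, reads of a fixed even length fall into four
classes:

* **A** — first half purely intergenic (upstream), second half the start
  of a gene, with the gene beginning exactly at the read midpoint;
* **B** — fully inside one gene (may contain the start or stop codon when
  the window abuts a gene boundary);
* **C** — first half the final bases of a gene, second half purely
  intergenic (downstream);
* **D** — fully intergenic.

Candidate enumeration is exhaustive; sampling is uniform without
replacement across the pooled candidates of all genomes.  Reads from
reverse-strand genes are reverse-complemented so the coding strand is the
read's forward strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from fragbench.errors import ConfigurationError, FormatError, PoolShortfallError
from fragbench.syngen import AnnotatedGenome

FRAGMENT_TYPES = ("A", "B", "C", "D")

TRUTH_COLUMNS = [
    "read_id",
    "ftype",
    "read_length",
    "truth_start",
    "truth_end",
    "genome_id",
    "genome_start",
    "genome_end",
    "strand",
]


class Candidate(NamedTuple):
    """A genome window that yields one fragment of a given type.

    start/end are 0-based half-open genome coordinates of the window;
    strand is the coding strand ('-' means the emitted read is the
    reverse complement of the genomic window); gene_start/gene_end give
    the source gene, or (-1, -1) for type D.
    """

    start: int
    end: int
    strand: str
    gene_start: int
    gene_end: int


@dataclass(frozen=True)
class Fragment:
    """One simulated read with its ground truth.

    truth_interval is in 0-based half-open read coordinates, None for
    type D.  source_gene holds the contributing gene's genome interval.
    """

    read_id: str
    sequence: str
    ftype: str
    read_length: int
    truth_interval: tuple[int, int] | None
    genome_id: str
    genome_start: int
    genome_end: int
    strand: str
    source_gene: tuple[int, int] | None

    @property
    def is_coding(self) -> bool:
        return self.truth_interval is not None


@dataclass(frozen=True)
class BenchmarkSet:
    """Fragments stratified by (read_length, ftype), plus the design."""

    fragments: tuple[Fragment, ...]
    read_lengths: tuple[int, ...]
    n_per_type: int
    seed: int
    provenance: str = ""

    def stratum(self, read_length: int | None = None, ftype: str | None = None) -> list[Fragment]:
        return [
            f
            for f in self.fragments
            if (read_length is None or f.read_length == read_length)
            and (ftype is None or f.ftype == ftype)
        ]

    def coding_fraction(self) -> float:
        return sum(f.is_coding for f in self.fragments) / len(self.fragments)

    def by_id(self) -> dict[str, Fragment]:
        return {f.read_id: f for f in self.fragments}


def _intergenic_runs(genome: AnnotatedGenome) -> list[tuple[int, int]]:
    """Maximal intergenic intervals, 0-based half-open."""
    runs = []
    pos = 0
    for start, end, _ in genome.genes:
        if start > pos:
            runs.append((pos, start))
        pos = end
    if pos < len(genome.sequence):
        runs.append((pos, len(genome.sequence)))
    return runs


def find_candidates(genome: AnnotatedGenome, read_length: int, ftype: str) -> list[Candidate]:
    """Enumerate every genome window that yields a fragment of `ftype`.

    Types A and C are anchored at the gene's 5' start and 3' end
    respectively (upstream half + first half-read of the gene; last
    half-read of the gene + downstream half), type B windows lie fully
    inside one gene, and type D windows are fully intergenic.
    """
    if read_length % 2 != 0 or read_length < 2:
        raise ConfigurationError(
            f"read_length must be even and >= 2 (half/half gene-edge design), got {read_length}"
        )
    if ftype not in FRAGMENT_TYPES:
        raise ConfigurationError(f"unknown fragment type {ftype!r}")
    L = read_length
    h = L // 2
    n = len(genome.sequence)
    mask = genome.coding_mask()
    out: list[Candidate] = []

    def intergenic(a: int, b: int) -> bool:
        return a >= 0 and b <= n and not mask[a:b].any()

    if ftype in ("A", "C"):
        for gs, ge, strand in genome.genes:
            if ge - gs < h:
                continue
            if ftype == "A":
                # window covering the gene's 5' start and the upstream flank
                if strand == "+" and intergenic(gs - h, gs):
                    out.append(Candidate(gs - h, gs + h, "+", gs, ge))
                elif strand == "-" and intergenic(ge, ge + h):
                    out.append(Candidate(ge - h, ge + h, "-", gs, ge))
            else:
                # window covering the gene's 3' end and the downstream flank
                if strand == "+" and intergenic(ge, ge + h):
                    out.append(Candidate(ge - h, ge + h, "+", gs, ge))
                elif strand == "-" and intergenic(gs - h, gs):
                    out.append(Candidate(gs - h, gs + h, "-", gs, ge))
    elif ftype == "B":
        for gs, ge, strand in genome.genes:
            for s in range(gs, ge - L + 1):
                out.append(Candidate(s, s + L, strand, gs, ge))
    else:  # D
        for a, b in _intergenic_runs(genome):
            for s in range(a, b - L + 1):
                out.append(Candidate(s, s + L, "+", -1, -1))
    return out


def _truth_interval(ftype: str, read_length: int) -> tuple[int, int] | None:
    h = read_length // 2
    if ftype == "A":
        return (h, read_length)
    if ftype == "B":
        return (0, read_length)
    if ftype == "C":
        return (0, h)
    return None


def _make_fragment(
    genome: AnnotatedGenome, cand: Candidate, read_length: int, ftype: str
) -> Fragment:
    seq = genome.sequence[cand.start : cand.end]
    if cand.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    read_id = f"{genome.id}|{cand.start}|{cand.strand}|{ftype}|{read_length}"
    return Fragment(
        read_id=read_id,
        sequence=seq,
        ftype=ftype,
        read_length=read_length,
        truth_interval=_truth_interval(ftype, read_length),
        genome_id=genome.id,
        genome_start=cand.start,
        genome_end=cand.end,
        strand=cand.strand,
        source_gene=None if ftype == "D" else (cand.gene_start, cand.gene_end),
    )


def sample_fragments(
    genomes: Sequence[AnnotatedGenome],
    read_length: int,
    ftype: str,
    n: int,
    seed: int | np.random.SeedSequence,
    allow_replacement: bool = False,
) -> list[Fragment]:
    """Sample `n` fragments uniformly from the pooled candidates of all genomes.

    Without replacement by default; a pool smaller than `n` raises
    PoolShortfallError naming the shortfall unless allow_replacement is set.
    """
    pools = [(g, find_candidates(g, read_length, ftype)) for g in genomes]
    sizes = [len(c) for _, c in pools]
    total = sum(sizes)
    if total == 0:
        raise PoolShortfallError(
            f"no candidates for type {ftype} at read length {read_length}"
        )
    if total < n and not allow_replacement:
        raise PoolShortfallError(
            f"type {ftype}, read length {read_length}: pool has {total} candidates "
            f"but {n} requested (short by {n - total}); "
            "set allow_replacement to sample with replacement"
        )
    if total < n:
        logging.getLogger("fragbench").warning(
            "type %s, read length %d: pool %d < %d requested; sampling with replacement",
            ftype, read_length, total, n,
        )
    rng = np.random.default_rng(seed)
    # without replacement whenever the pool suffices, even if replacement is allowed
    idx = rng.choice(total, size=n, replace=total < n)
    offsets = np.cumsum([0] + sizes)
    out = []
    for i in sorted(int(j) for j in idx):
        k = int(np.searchsorted(offsets, i, side="right")) - 1
        genome, cands = pools[k]
        out.append(_make_fragment(genome, cands[i - offsets[k]], read_length, ftype))
    return out


def build_benchmark(
    genomes: Sequence[AnnotatedGenome],
    read_lengths: Iterable[int],
    n_per_type: int,
    seed: int,
    allow_replacement: bool = False,
) -> BenchmarkSet:
    """Build the full stratified benchmark: |read_lengths| x 4 x n_per_type reads.

    Each (read_length, ftype) stratum draws from its own deterministically
    derived child seed, so strata are independent of each other's sizes.
    """
    read_lengths = tuple(sorted(set(int(x) for x in read_lengths)))
    for L in read_lengths:
        if L % 2 != 0:
            raise ConfigurationError(f"read lengths must be even, got {L}")
    master = np.random.SeedSequence(seed)
    children = master.spawn(len(read_lengths) * len(FRAGMENT_TYPES))
    fragments: list[Fragment] = []
    i = 0
    for L in read_lengths:
        for ftype in FRAGMENT_TYPES:
            fragments.extend(
                sample_fragments(
                    genomes, L, ftype, n_per_type, children[i], allow_replacement
                )
            )
            i += 1
    return BenchmarkSet(
        fragments=tuple(fragments),
        read_lengths=read_lengths,
        n_per_type=n_per_type,
        seed=seed,
        provenance=",".join(g.id for g in genomes),
    )


def write_benchmark(bench: BenchmarkSet, fasta_path, truth_path) -> None:
    """Write fragment sequences (FASTA) and the truth table (TSV).

    Truth coordinates are written 1-based inclusive; type D rows carry "."
    in both truth columns.
    """
    records = [
        SeqRecord(Seq(f.sequence), id=f.read_id, description="") for f in bench.fragments
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = []
    for f in bench.fragments:
        if f.truth_interval is None:
            ts, te = ".", "."
        else:
            ts, te = str(f.truth_interval[0] + 1), str(f.truth_interval[1])
        rows.append(
            (
                f.read_id,
                f.ftype,
                f.read_length,
                ts,
                te,
                f.genome_id,
                f.genome_start + 1,
                f.genome_end,
                f.strand,
            )
        )
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(truth_path, sep="\t", index=False)


def read_benchmark(fasta_path, truth_path) -> BenchmarkSet:
    """Read a benchmark written by write_benchmark; validates type invariants."""
    seqs = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta_path), "fasta")}
    df = pd.read_csv(truth_path, sep="\t", dtype=str)
    if list(df.columns) != TRUTH_COLUMNS:
        raise FormatError(f"{truth_path}: expected columns {TRUTH_COLUMNS}")
    fragments = []
    lengths: set[int] = set()
    counts: dict[tuple[int, str], int] = {}
    for row in df.itertuples(index=False):
        L = int(row.read_length)
        if row.truth_start == "." or row.truth_end == ".":
            truth = None
        else:
            truth = (int(row.truth_start) - 1, int(row.truth_end))
        expected = _truth_interval(row.ftype, L)
        if truth != expected:
            raise FormatError(
                f"{truth_path}: read {row.read_id} type {row.ftype} has truth "
                f"{truth}, expected {expected}"
            )
        seq = seqs.get(row.read_id)
        if seq is None:
            raise FormatError(f"{truth_path}: read {row.read_id} missing from FASTA")
        gs, ge = int(row.genome_start) - 1, int(row.genome_end)
        fragments.append(
            Fragment(
                read_id=row.read_id,
                sequence=seq,
                ftype=row.ftype,
                read_length=L,
                truth_interval=truth,
                genome_id=row.genome_id,
                genome_start=gs,
                genome_end=ge,
                strand=row.strand,
                source_gene=None,
            )
        )
        lengths.add(L)
        counts[(L, row.ftype)] = counts.get((L, row.ftype), 0) + 1
    n_per_type = max(counts.values()) if counts else 0
    return BenchmarkSet(
        fragments=tuple(fragments),
        read_lengths=tuple(sorted(lengths)),
        n_per_type=n_per_type,
        seed=-1,
    )
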