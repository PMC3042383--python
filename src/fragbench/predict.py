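"""Per-read gene predictions: ingestion, a log-odds ORF baseline, and mocks.

A prediction for a read is zero or more coding intervals in 0-based
half-open read coordinates; a read with any interval is called coding,
and a read absent from a prediction set is non-coding.  External
predictors' outputs are ingested from a GFF3 or TSV dialect (1-based
inclusive on disk).  The built-in baseline scores open reading frames by
mean per-codon log-odds (log2 of coding over background codon frequency)
in all six frames, keeping edge-incomplete ORFs that lack a start and/or
stop at the read boundaries.  Mock predictors with tunable per-read
sensitivity, specificity and coordinate noise exercise the combination
machinery without any external tool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio.Seq import Seq

from fragbench import codons
from fragbench.errors import FormatError, TrainingError
from fragbench.fragsim import BenchmarkSet, Fragment
from fragbench.syngen import AnnotatedGenome


@dataclass(frozen=True)
class Interval:
    """One predicted coding interval on a read (0-based half-open)."""

    start: int
    end: int
    strand: str = "+"
    score: float | None = None

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"bad interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GenePrediction:
    """One predictor's output on one read."""

    read_id: str
    intervals: tuple[Interval, ...] = ()

    @property
    def is_coding(self) -> bool:
        return len(self.intervals) > 0

    def selected_interval(
        self, truth_interval: tuple[int, int] | None = None
    ) -> Interval | None:
        """The interval used for annotation error and coordinate combination.

        With truth available: maximal overlap with the reference gene;
        otherwise highest score.  Ties break to the longest, then the
        leftmost interval.
        """
        if not self.intervals:
            return None
        if truth_interval is not None:
            ts, te = truth_interval

            def key(iv: Interval):
                overlap = max(0, min(iv.end, te) - max(iv.start, ts))
                return (-overlap, -iv.length, iv.start)

        else:

            def key(iv: Interval):
                score = iv.score if iv.score is not None else float("-inf")
                return (-score, -iv.length, iv.start)

        return min(self.intervals, key=key)


@dataclass
class PredictionSet:
    """A named predictor's calls over a read set.

    A read_id missing from `predictions` is a non-coding call.
    """

    predictor_name: str
    predictions: dict[str, GenePrediction] = field(default_factory=dict)

    def get(self, read_id: str) -> GenePrediction:
        return self.predictions.get(read_id, GenePrediction(read_id=read_id))

    def is_coding(self, read_id: str) -> bool:
        return self.get(read_id).is_coding

    def validate_against(self, bench: BenchmarkSet) -> None:
        by_id = bench.by_id()
        for read_id, pred in self.predictions.items():
            frag = by_id.get(read_id)
            if frag is None:
                raise FormatError(
                    f"{self.predictor_name}: prediction for unknown read {read_id}"
                )
            for iv in pred.intervals:
                if iv.end > frag.read_length:
                    raise FormatError(
                        f"{self.predictor_name}: read {read_id} interval "
                        f"[{iv.start}, {iv.end}) exceeds read length {frag.read_length}"
                    )


# ---------------------------------------------------------------------------
# ingestion / serialization

TSV_COLUMNS = ["read_id", "start", "end", "strand", "score"]


def _add_interval(preds: dict[str, list[Interval]], read_id, start1, end1, strand, score):
    iv = Interval(start=int(start1) - 1, end=int(end1), strand=strand, score=score)
    preds.setdefault(read_id, []).append(iv)


def parse_predictions(path, format: str = "tsv", predictor_name: str | None = None) -> PredictionSet:
    """Read a prediction file (GFF3 or TSV dialect, 1-based inclusive).

    GFF3: seqid = read_id, one feature row per predicted interval, the
    score column in bits/codon.  TSV: columns read_id, start, end,
    strand, score.  Reads with no row are non-coding.
    """
    name = predictor_name or str(path)
    raw: dict[str, list[Interval]] = {}
    if format == "gff3":
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
        for feat in db.all_features():
            score = None if feat.score in (".", "", None) else float(feat.score)
            _add_interval(raw, feat.seqid, feat.start, feat.end, feat.strand or "+", score)
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        missing = [c for c in TSV_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing columns {missing}")
        for row in df.itertuples(index=False):
            score = None if row.score in (".", "", None) or pd.isna(row.score) else float(row.score)
            _add_interval(raw, row.read_id, row.start, row.end, row.strand, score)
    else:
        raise FormatError(f"unknown prediction format {format!r}")
    return PredictionSet(
        predictor_name=name,
        predictions={
            rid: GenePrediction(read_id=rid, intervals=tuple(ivs))
            for rid, ivs in raw.items()
        },
    )


def write_predictions(pset: PredictionSet, path, format: str = "tsv") -> None:
    """Write a prediction set in the GFF3 or TSV dialect (1-based inclusive)."""
    if format == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            i = 0
            for rid in sorted(pset.predictions):
                for iv in pset.predictions[rid].intervals:
                    score = "." if iv.score is None else f"{iv.score:.4f}"
                    fh.write(
                        "\t".join(
                            [
                                rid,
                                pset.predictor_name,
                                "CDS",
                                str(iv.start + 1),
                                str(iv.end),
                                score,
                                iv.strand,
                                ".",
                                f"ID=pred_{i:06d}",
                            ]
                        )
                        + "\n"
                    )
                    i += 1
    elif format == "tsv":
        rows = []
        for rid in sorted(pset.predictions):
            for iv in pset.predictions[rid].intervals:
                score = "." if iv.score is None else f"{iv.score:.4f}"
                rows.append((rid, iv.start + 1, iv.end, iv.strand, score))
        pd.DataFrame(rows, columns=TSV_COLUMNS).to_csv(path, sep="\t", index=False)
    else:
        raise FormatError(f"unknown prediction format {format!r}")


# ---------------------------------------------------------------------------
# log-odds codon model baseline


@dataclass(frozen=True)
class CodonModel:
    """64-entry codon log-odds table against a mononucleotide background.

    scores[i] = log2(coding frequency / background frequency) of codon i
    (CODONS order), pseudocount-smoothed so all entries are finite.
    """

    scores: np.ndarray
    background: np.ndarray  # mononucleotide probs, ACGT order
    min_orf_len: int = 60
    score_threshold: float = 0.1  # bits per codon


def train_codon_model(
    genomes: Sequence[AnnotatedGenome],
    pseudocount: float = 1.0,
    min_orf_len: int = 60,
    score_threshold: float = 0.1,
) -> CodonModel:
    """Tally in-frame codon usage over annotated genes vs. the genome background.

    The background codon frequency is the product of the genome-wide
    mononucleotide frequencies; both distributions are pseudocount-smoothed
    and normalized before the base-2 log ratio.
    """
    counts = np.zeros(64)
    base_counts = np.zeros(4)
    coding_bp = 0
    for genome in genomes:
        for b, i in codons.BASE_INDEX.items():
            base_counts[i] += genome.sequence.count(b)
        for gs, ge, strand in genome.genes:
            seq = genome.sequence[gs:ge]
            if strand == "-":
                seq = str(Seq(seq).reverse_complement())
            idx = codons.codon_indices(seq)
            idx = idx[idx >= 0]
            np.add.at(counts, idx, 1)
            coding_bp += ge - gs
    if coding_bp == 0:
        raise TrainingError("no annotated genes to train on")
    if coding_bp < 3000:
        raise TrainingError(
            f"only {coding_bp} coding bp available; need >= 3000 for a stable table"
        )
    total = counts.sum()
    background = base_counts / base_counts.sum()
    bg_codon = np.empty(64)
    for i, codon in enumerate(codons.CODONS):
        bg_codon[i] = np.prod([background[codons.BASE_INDEX[b]] for b in codon])
    coding_p = (counts + pseudocount) / (total + 64 * pseudocount)
    bg_p = (bg_codon * total + pseudocount) / (total + 64 * pseudocount)
    return CodonModel(
        scores=np.log2(coding_p / bg_p),
        background=background,
        min_orf_len=min_orf_len,
        score_threshold=score_threshold,
    )


def score_sequence(model: CodonModel, sequence: str, frame: int = 0) -> float:
    """Mean per-codon log-odds of a sequence in the given frame (bits/codon)."""
    idx = codons.codon_indices(sequence, frame)
    idx = idx[idx >= 0]
    if len(idx) == 0:
        return float("nan")
    return float(model.scores[idx].mean())


def _frame_segments(idx: np.ndarray) -> list[tuple[int, int]]:
    """Maximal stop-free codon runs [i, j) in a frame's codon index array."""
    is_stop = np.isin(idx, [codons.CODON_INDEX[s] for s in codons.STOP_CODONS])
    segments = []
    start = 0
    for i, stop in enumerate(is_stop):
        if stop:
            if i > start:
                segments.append((start, i))
            start = i + 1
    if len(idx) > start:
        segments.append((start, len(idx)))
    return segments


def baseline_orf_predictor(
    fragments: Iterable[Fragment], model: CodonModel, name: str = "logodds"
) -> PredictionSet:
    """Score stop-free stretches in all six frames; keep those passing the model.

    Candidate stretches include edge-incomplete ORFs that run off either
    read boundary (short-read fragments usually lack a start and/or stop).
    An interval is emitted when its mean codon log-odds reaches the model
    threshold and its length reaches min_orf_len; all passing intervals
    are kept per read.
    """
    predictions: dict[str, GenePrediction] = {}
    for frag in fragments:
        L = len(frag.sequence)
        ivs: list[Interval] = []
        for strand, seq in (("+", frag.sequence), ("-", str(Seq(frag.sequence).reverse_complement()))):
            for frame in range(3):
                idx = codons.codon_indices(seq, frame)
                for i, j in _frame_segments(idx):
                    seg = idx[i:j]
                    seg = seg[seg >= 0]
                    if len(seg) == 0:
                        continue
                    bp = 3 * (j - i)
                    if bp < model.min_orf_len:
                        continue
                    score = float(model.scores[seg].mean())
                    if score < model.score_threshold:
                        continue
                    s = frame + 3 * i
                    e = frame + 3 * j
                    if strand == "-":
                        s, e = L - e, L - s
                    ivs.append(Interval(start=s, end=e, strand=strand, score=score))
        if ivs:
            predictions[frag.read_id] = GenePrediction(
                read_id=frag.read_id, intervals=tuple(ivs)
            )
    return PredictionSet(predictor_name=name, predictions=predictions)


# ---------------------------------------------------------------------------
# mock predictors


def mock_predictor(
    truth: BenchmarkSet | Sequence[Fragment],
    sens: float,
    spec: float,
    coord_noise_sd: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
    name: str | None = None,
) -> PredictionSet:
    """A seeded test double with nominal per-read sensitivity and specificity.

    Each coding-truth read is called coding with probability `sens`, in
    which case its truth interval is emitted with endpoints perturbed by
    rounded Gaussian noise (sd = coord_noise_sd bp) clipped to the read;
    each non-coding read is called coding with probability 1 - `spec`,
    with a uniformly random interval.  Deterministic given the seed.
    """
    if not (0 <= sens <= 1 and 0 <= spec <= 1 and coord_noise_sd >= 0):
        raise ValueError("sens, spec must be in [0, 1]; coord_noise_sd >= 0")
    fragments = truth.fragments if isinstance(truth, BenchmarkSet) else truth
    rng = np.random.default_rng(seed)
    predictions: dict[str, GenePrediction] = {}
    for frag in fragments:
        L = frag.read_length
        if frag.truth_interval is not None:
            if rng.random() >= sens:
                continue
            s, e = frag.truth_interval
            if coord_noise_sd > 0:
                s = int(np.clip(round(s + rng.normal(0, coord_noise_sd)), 0, L - 1))
                e = int(np.clip(round(e + rng.normal(0, coord_noise_sd)), s + 1, L))
        else:
            if rng.random() >= 1.0 - spec:
                continue
            a, b = sorted(int(x) for x in rng.integers(0, L, size=2))
            s, e = a, b + 1
        predictions[frag.read_id] = GenePrediction(
            read_id=frag.read_id, intervals=(Interval(start=s, end=e),)
        )
    if name is None:
        name = f"mock(sens={sens:g},spec={spec:g},sd={coord_noise_sd:g})"
    return PredictionSet(predictor_name=name, predictions=predictions)


def oracle_predictor(truth: BenchmarkSet, name: str = "oracle") -> PredictionSet:
    """The perfect predictor: emits exactly the truth interval of every coding read."""
    return mock_predictor(truth, sens=1.0, spec=1.0, coord_noise_sd=0.0, seed=0, name=name)
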