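"""Boolean and majority-vote combination of gene predictors.

Predictors are combined at two levels: the binary level (is the read
coding at all?) via AND / OR / strict-majority consensus, and the
coordinate level, where member intervals are intersected (AND), unioned
(OR), or aggregated by coordinate-wise median (consensus).  The classical
ensemble inequalities — union sensitivity dominates members,
intersection specificity dominates members — and the upper-bound error
(the fraction of reads every member gets wrong) quantify what combination
can and cannot buy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from fragbench.fragsim import BenchmarkSet
from fragbench.predict import GenePrediction, Interval, PredictionSet

OPS = ("AND", "OR", "CONSENSUS")


@dataclass(frozen=True)
class CombinationRule:
    """A Boolean combination over named member predictors."""

    op: str  # AND | OR | CONSENSUS
    members: tuple[str, ...]

    def __post_init__(self):
        if self.op not in OPS:
            raise ValueError(f"unknown op {self.op!r}; expected one of {OPS}")
        if len(self.members) < 2:
            raise ValueError("a combination needs at least 2 members")
        if self.op == "CONSENSUS" and (len(self.members) < 3 or len(self.members) % 2 == 0):
            raise ValueError(
                "CONSENSUS needs an odd number of members >= 3 for a strict majority"
            )

    @property
    def name(self) -> str:
        return f"{self.op}({','.join(self.members)})"


def combine_binary(calls: Sequence[bool], rule: CombinationRule) -> bool:
    """Combine member coding calls: AND = all, OR = any, CONSENSUS = strict majority."""
    if len(calls) != len(rule.members):
        raise ValueError(
            f"{rule.name}: got {len(calls)} calls for {len(rule.members)} members"
        )
    if rule.op == "AND":
        return all(calls)
    if rule.op == "OR":
        return any(calls)
    return sum(bool(c) for c in calls) * 2 > len(calls)


def combine_intervals(
    preds: Sequence[GenePrediction],
    rule: CombinationRule,
    read_length: int,
    truth_interval: tuple[int, int] | None = None,
) -> tuple[GenePrediction, bool]:
    """Coordinate-level combination of the members' selected intervals.

    Returns (combined prediction, disjoint flag).  The read is coding iff
    the binary combination of the members' calls is true.  AND intersects
    the members' selected intervals — an empty intersection yields a
    coding call with no interval, flagged disjoint; OR takes the
    enclosing hull of the coding members' intervals; CONSENSUS takes the
    coordinate-wise median over the coding members' endpoints (lower
    median on even counts).
    """
    read_id = preds[0].read_id if preds else ""
    calls = [p.is_coding for p in preds]
    if not combine_binary(calls, rule):
        return GenePrediction(read_id=read_id), False
    chosen = [
        p.selected_interval(truth_interval) for p in preds if p.is_coding
    ]
    chosen = [iv for iv in chosen if iv is not None]
    if rule.op == "AND":
        left = max(iv.start for iv in chosen)
        right = min(iv.end for iv in chosen)
        if left >= right:
            return GenePrediction(read_id=read_id), True
        interval = Interval(start=left, end=right)
    elif rule.op == "OR":
        interval = Interval(
            start=min(iv.start for iv in chosen),
            end=max(iv.end for iv in chosen),
        )
    else:  # CONSENSUS: coordinate-wise lower median over coding members
        lefts = sorted(iv.start for iv in chosen)
        rights = sorted(iv.end for iv in chosen)
        k = (len(chosen) - 1) // 2
        left, right = lefts[k], rights[k]
        if left >= right:
            return GenePrediction(read_id=read_id), True
        interval = Interval(start=left, end=right)
    return GenePrediction(read_id=read_id, intervals=(interval,)), False


def combine_predictions(
    members: Sequence[PredictionSet],
    rule: CombinationRule,
    bench: BenchmarkSet | None = None,
    read_ids: Sequence[str] | None = None,
    read_lengths: Mapping[str, int] | None = None,
) -> tuple[PredictionSet, int]:
    """Apply a combination rule read-by-read over whole prediction sets.

    Reads are taken from the benchmark (whose truth intervals then guide
    interval selection) or from an explicit read_ids list.  Returns the
    combined PredictionSet (named after the rule) and the count of reads
    whose AND/consensus intervals were disjoint (coding call, no
    coordinates).
    """
    by_name = {m.predictor_name: m for m in members}
    missing = [name for name in rule.members if name not in by_name]
    if missing:
        raise ValueError(f"{rule.name}: member predictions missing for {missing}")
    ordered = [by_name[name] for name in rule.members]
    if bench is not None:
        frags = bench.fragments
        ids = [f.read_id for f in frags]
        truths = {f.read_id: f.truth_interval for f in frags}
        lengths = {f.read_id: f.read_length for f in frags}
    else:
        if read_ids is None:
            raise ValueError("need a benchmark or an explicit read_ids list")
        ids = list(read_ids)
        truths = {}
        lengths = dict(read_lengths or {})
    predictions: dict[str, GenePrediction] = {}
    n_disjoint = 0
    for rid in ids:
        preds = [m.get(rid) for m in ordered]
        combined, disjoint = combine_intervals(
            preds, rule, lengths.get(rid, 0), truths.get(rid)
        )
        n_disjoint += disjoint
        if combined.is_coding or disjoint:
            # disjoint reads keep an interval-free coding record so the
            # binary call survives; metrics exclude them from annotation error
            predictions[rid] = GenePrediction(
                read_id=rid, intervals=combined.intervals
            ) if combined.is_coding else _CodingNoInterval(rid)
    return PredictionSet(predictor_name=rule.name, predictions=predictions), n_disjoint


class _CodingNoInterval(GenePrediction):
    """A coding binary call whose coordinates could not be combined."""

    def __init__(self, read_id: str):
        super().__init__(read_id=read_id, intervals=())

    @property
    def is_coding(self) -> bool:  # binary call stays positive
        return True


def upper_bound_flags(
    calls_by_predictor: Mapping[str, Mapping[str, bool]],
    truth: Mapping[str, bool],
) -> dict[str, bool]:
    """Per-read correctness flags of the best-case combiner.

    A read is marked correct iff at least one member predictor's binary
    call equals the truth; the fraction of incorrect reads is the
    upper-bound prediction error — the error floor for any combiner of
    these members.
    """
    read_sets = {name: set(calls.keys()) for name, calls in calls_by_predictor.items()}
    truth_ids = set(truth.keys())
    for name, ids in read_sets.items():
        if ids != truth_ids:
            diff = sorted(ids.symmetric_difference(truth_ids))[:10]
            raise ValueError(
                f"predictor {name} read set differs from truth; "
                f"symmetric difference starts with {diff}"
            )
    return {
        rid: any(calls[rid] == truth[rid] for calls in calls_by_predictor.values())
        for rid in truth_ids
    }


def upper_bound_error(
    calls_by_predictor: Mapping[str, Mapping[str, bool]],
    truth: Mapping[str, bool],
) -> float:
    """Fraction of reads on which every member predictor is wrong."""
    flags = upper_bound_flags(calls_by_predictor, truth)
    return 1.0 - sum(flags.values()) / len(flags)
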