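"""Codon tables and GC-parameterized codon distributions.

Shared by the synthetic-genome generator (which draws gene bodies codon by
codon) and the log-odds baseline predictor (which scores codons against a
background model).
"""

from __future__ import annotations

import itertools

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: All 64 codons in lexicographic order over A<C<G<T.
CODONS: tuple[str, ...] = tuple(
    "".join(c) for c in itertools.product(BASES, repeat=3)
)
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

STOP_CODONS = ("TAA", "TAG", "TGA")
START_CODON = "ATG"

#: The 61 sense (non-stop) codons, in CODONS order.
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in CODONS if c not in STOP_CODONS
)
SENSE_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}


def mononucleotide_probs(gc: float) -> np.ndarray:
    """Per-base probabilities (A, C, G, T order) at a target GC fraction."""
    if not 0.0 < gc < 1.0:
        raise ValueError(f"gc must be in (0, 1), got {gc}")
    at = (1.0 - gc) / 2.0
    g = gc / 2.0
    return np.array([at, g, g, at])


def codon_product_probs(gc: float) -> np.ndarray:
    """Probability of each of the 64 codons under independent bases at `gc`."""
    p = mononucleotide_probs(gc)
    out = np.empty(64)
    for i, codon in enumerate(CODONS):
        out[i] = p[BASE_INDEX[codon[0]]] * p[BASE_INDEX[codon[1]]] * p[BASE_INDEX[codon[2]]]
    return out


def _same_composition_sense(codon: str) -> list[str]:
    key = "".join(sorted(codon))
    return [c for c in SENSE_CODONS if "".join(sorted(c)) == key]


def sense_codon_probs(gc: float) -> np.ndarray:
    """Stop-free codon distribution whose mononucleotide marginal is exact.

    Starting from the independent-bases codon distribution at the target GC,
    each stop codon's mass is redistributed uniformly over the sense codons
    with the same base multiset (TAA -> {AAT, ATA}; TAG, TGA -> the four
    sense permutations of {A, G, T}).  Because permutations of a multiset
    share the same product probability, the marginal base composition of
    sequences drawn from this table equals the intergenic background exactly
    — so zero codon bias really means indistinguishable composition, while
    gene bodies stay free of in-frame stops.
    """
    full = codon_product_probs(gc)
    probs = {c: full[CODON_INDEX[c]] for c in SENSE_CODONS}
    for stop in STOP_CODONS:
        targets = _same_composition_sense(stop)
        share = full[CODON_INDEX[stop]] / len(targets)
        for t in targets:
            probs[t] += share
    out = np.array([probs[c] for c in SENSE_CODONS])
    return out / out.sum()


def stop_codon_probs(gc: float) -> np.ndarray:
    """Relative probabilities of TAA, TAG, TGA at the target GC."""
    full = codon_product_probs(gc)
    p = np.array([full[CODON_INDEX[s]] for s in STOP_CODONS])
    return p / p.sum()


# Fixed "preferred codon" table used as the biased endpoint of the mixture
# that models codon-usage bias.  The log-weights are frozen constants (drawn
# once from a seeded generator and inlined by value via the seed) so the
# table is part of the package definition, not of any run's random stream.
_BIAS_LOGWEIGHTS = np.random.default_rng(20100421).normal(0.0, 1.5, size=len(SENSE_CODONS))


def biased_codon_probs() -> np.ndarray:
    """The fixed biased codon-usage table over the 61 sense codons."""
    w = np.exp(_BIAS_LOGWEIGHTS)
    return w / w.sum()


def gene_body_codon_probs(gc: float, codon_bias_strength: float) -> np.ndarray:
    """Mixture of the at-GC stop-free table and the fixed biased table.

    `codon_bias_strength` acts as the mixture weight, clipped to [0, 1]:
    0 gives background composition, 1 gives the fully biased table.
    """
    if codon_bias_strength < 0:
        raise ValueError("codon_bias_strength must be >= 0")
    w = min(codon_bias_strength, 1.0)
    return (1.0 - w) * sense_codon_probs(gc) + w * biased_codon_probs()


def codon_indices(sequence: str, frame: int = 0) -> np.ndarray:
    """Indices into CODONS for successive codons of `sequence` from `frame`.

    Codons containing non-ACGT characters are returned as -1.
    """
    s = sequence[frame:]
    n = len(s) // 3
    if n == 0:
        return np.empty(0, dtype=np.int64)
    arr = np.frombuffer(s[: 3 * n].encode("ascii"), dtype=np.uint8)
    lut = np.full(256, -1, dtype=np.int64)
    for b, i in BASE_INDEX.items():
        lut[ord(b)] = i
    base_idx = lut[arr].reshape(n, 3)
    bad = (base_idx < 0).any(axis=1)
    out = base_idx[:, 0] * 16 + base_idx[:, 1] * 4 + base_idx[:, 2]
    out[bad] = -1
    return out
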