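"""Global protein alignment helpers used by dereplication and graph building.

All identity computations in the package go through :func:`pairwise_identity`
so the convention is fixed in one place: global Needleman-Wunsch alignment
under BLOSUM62 with gap open 11 / extend 1, identity defined as the number
of exact matches divided by the length of the shorter sequence.  Only the
match count (never the raw score) feeds identity thresholds; raw scores are
used for similarity-graph weighting, normalized by self-scores.
"""

from __future__ import annotations

from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


_ALIGNER = _make_aligner()


def global_alignment_score(a: str, b: str) -> float:
    """BLOSUM62 global alignment score of two protein sequences."""
    return float(_ALIGNER.score(a, b))


@lru_cache(maxsize=65536)
def self_score(seq: str) -> float:
    """Score of a sequence aligned to itself (no gaps open)."""
    return float(_ALIGNER.score(seq, seq))


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical aligned residues over the shorter sequence.

    The shorter-sequence denominator mirrors the convention of greedy
    incremental dereplication tools, where a fragment identical over its
    full length to a longer sequence counts as 100% identical.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    alignment = _ALIGNER.align(a, b)[0]
    identities = alignment.counts().identities
    return identities / min(len(a), len(b))
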