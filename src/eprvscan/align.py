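"""Shared pairwise protein alignment helpers.

All stages of the pipeline score protein alignments with the same
conventions as the translated-search tool they emulate: BLOSUM62, gap
open 11, gap extension 1. Alignments are delegated to
:class:`Bio.Align.PairwiseAligner`; this module only fixes the scoring
conventions and exposes the handful of derived quantities the pipeline
needs (raw/bit scores, identity fractions, p-distances).
"""

from __future__ import annotations

import math
from functools import lru_cache

from Bio.Align import PairwiseAligner, substitution_matrices

# Karlin-Altschul parameters for gapped BLOSUM62 (open 11 / extend 1),
# as tabulated for protein database search statistics.
KA_LAMBDA = 0.267
KA_K = 0.041

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1

# 20 canonical residues; 'X' (unknown) and '*' (stop) are scoreable under
# BLOSUM62 but are never valid in reference or candidate peptides.
AA20 = "ACDEFGHIKLMNPQRSTVWY"


@lru_cache(maxsize=8)
def get_aligner(
    mode: str = "local",
    matrix: str = DEFAULT_MATRIX,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> PairwiseAligner:
    """Return a cached aligner with BLAST-convention affine gap costs.

    A gap of length k costs ``gap_open + k * gap_extend``.
    """
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    aligner.mode = mode
    return aligner


def local_align(subject: str, query: str):
    """Best Smith-Waterman local alignment of query within subject.

    Returns the first optimal :class:`Bio.Align.Alignment` (target =
    subject), or None if no positively scoring alignment exists.
    """
    aligner = get_aligner("local")
    alignments = aligner.align(subject, query)
    if len(alignments) == 0:
        return None
    return alignments[0]


def local_score(subject: str, query: str) -> float:
    return get_aligner("local").score(subject, query)


def global_align(a: str, b: str):
    return get_aligner("global").align(a, b)[0]


def global_score(a: str, b: str) -> float:
    return get_aligner("global").score(a, b)


def global_identity_stats(a: str, b: str) -> tuple[int, int]:
    """(identities, mismatches) over the global alignment of a and b.

    Gap columns are excluded from both counts. The pair is put in
    lexicographic order before aligning: co-optimal alignments can differ
    in their identity/mismatch split, and the aligner's first optimum
    depends on argument order — canonicalising makes the derived identity
    and distance functions exactly symmetric.
    """
    if b < a:
        a, b = b, a
    counts = global_align(a, b).counts()
    return counts.identities, counts.mismatches


def pairwise_identity(a: str, b: str) -> float:
    """Fractional identity with the shorter sequence as denominator.

    This is the CD-HIT convention: identical aligned positions divided by
    the length of the shorter of the two sequences, so a perfect substring
    match scores 1.0. Symmetric; always in [0, 1].
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    identities, _ = global_identity_stats(a, b)
    return min(identities / min(len(a), len(b)), 1.0)


def p_distance(a: str, b: str) -> float:
    """Mismatch fraction over aligned (non-gap) columns of the global alignment."""
    identities, mismatches = global_identity_stats(a, b)
    aligned = identities + mismatches
    if aligned == 0:
        raise ValueError("no aligned columns between sequences")
    return mismatches / aligned


def bit_score(raw_score: float) -> float:
    """Karlin-Altschul bit score for a raw BLOSUM62 gapped score."""
    return (KA_LAMBDA * raw_score - math.log(KA_K)) / math.log(2.0)


def evalue(raw_score: float, query_len: int, search_space: int) -> float:
    """Expected number of chance alignments at this score.

    search_space is the total number of translated residues scanned
    (all six frames over all contigs).
    """
    return query_len * search_space * math.pow(2.0, -bit_score(raw_score))
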