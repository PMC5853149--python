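"""Pairwise alignment core for promoter synteny mapping and transcript
conservation.

Local (Smith-Waterman) and global (Needleman-Wunsch) alignments with affine
gaps are computed with Biopython's C PairwiseAligner under a custom ACGTN
substitution matrix in which N never matches anything (it scores as a
mismatch, even against N). Genome-wide promoter placement uses a
seed-and-refine strategy: edlib's semi-global (infix) edit-distance search
locates the best candidate locus on each chromosome and strand, and the
local aligner rescorees that window under the configured scoring scheme.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import edlib
import numpy as np
from Bio import Align

from .models import AlignmentResult, revcomp

#: Co-optimal alignments examined when breaking ties positionally.
_MAX_TRACEBACKS = 64


@dataclass(frozen=True)
class ScoringScheme:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0    # cost of the first gapped column
    gap_extend: float = -1.0  # cost of each further gapped column

    def __post_init__(self):
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("penalties must be <= 0")


def _substitution_matrix(scoring: ScoringScheme) -> Align.substitution_matrices.Array:
    alphabet = "ACGTN"
    mat = Align.substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            if a == b and a != "N":
                mat[a, b] = scoring.match
            else:
                mat[a, b] = scoring.mismatch
    return mat


def _make_aligner(scoring: ScoringScheme, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = _substitution_matrix(scoring)
    # open/extend apply to internal and end gaps alike
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def _check_seqs(*seqs: str) -> None:
    for seq in seqs:
        if not seq:
            raise ValueError("empty sequence")


def _alignment_stats(alignment) -> tuple[float, int]:
    """(identity, n_columns) over the alignment path; N-N is not a match."""
    row_a, row_b = alignment[0], alignment[1]
    matches = sum(1 for a, b in zip(row_a, row_b) if a == b and a not in "-N")
    n_cols = len(row_a)
    return (matches / n_cols if n_cols else 0.0), n_cols


def local_align(seq_a: str, seq_b: str,
                scoring: ScoringScheme | None = None) -> AlignmentResult:
    """Optimal affine-gap local alignment of two sequences.

    Ties among co-optimal alignments are broken by the lowest start in
    ``seq_a``, then in ``seq_b``. A best score <= 0 yields an empty result
    with score 0.
    """
    _check_seqs(seq_a, seq_b)
    scoring = scoring or ScoringScheme()
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    aligner = _make_aligner(scoring, "local")
    score = aligner.score(seq_a, seq_b)
    if score <= 0:
        return AlignmentResult(score=0.0, identity=0.0, n_aligned_columns=0)
    alignments = aligner.align(seq_a, seq_b)
    best = min(
        itertools.islice(alignments, _MAX_TRACEBACKS),
        key=lambda aln: (aln.aligned[0][0][0], aln.aligned[1][0][0]),
    )
    identity, n_cols = _alignment_stats(best)
    (a_start, a_end) = best.aligned[0][0][0], best.aligned[0][-1][1]
    (b_start, b_end) = best.aligned[1][0][0], best.aligned[1][-1][1]
    return AlignmentResult(
        score=float(score), identity=identity, n_aligned_columns=n_cols,
        query_start=int(a_start), query_end=int(a_end),
        target_start=int(b_start), target_end=int(b_end),
    )


def global_identity(seq_a: str, seq_b: str,
                    scoring: ScoringScheme | None = None) -> float:
    """End-to-end alignment identity: matches / alignment columns
    (gap columns included)."""
    _check_seqs(seq_a, seq_b)
    scoring = scoring or ScoringScheme()
    aligner = _make_aligner(scoring, "global")
    alignments = aligner.align(seq_a.upper(), seq_b.upper())
    identity, _ = _alignment_stats(alignments[0])
    return identity


def _edlib_locate(query: str, target: str) -> tuple[int, int] | None:
    """Best infix placement of `query` inside `target` by edit distance."""
    res = edlib.align(query, target, mode="HW", task="locations")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    start, end = res["locations"][0]
    return int(start), int(end) + 1  # edlib ends are inclusive


def best_genomic_hit(query_seq: str, genome: dict[str, str],
                     scoring: ScoringScheme | None = None,
                     min_identity: float = 0.6,
                     min_aligned: int = 100) -> AlignmentResult | None:
    """Best local alignment of a query against both strands of every
    chromosome.

    Returns ``None`` when the best hit has identity < ``min_identity`` or
    fewer than ``min_aligned`` aligned columns. The reported target interval
    is always on forward-strand coordinates; ``target_strand`` records the
    strand that aligned.
    """
    _check_seqs(query_seq)
    if len(query_seq) < min_aligned:
        raise ValueError("query shorter than min_aligned")
    scoring = scoring or ScoringScheme()
    query_seq = query_seq.upper()
    pad = max(20, len(query_seq) // 3)
    best: AlignmentResult | None = None
    for chrom in sorted(genome):
        forward = genome[chrom]
        for strand, target in (("+", forward), ("-", revcomp(forward))):
            loc = _edlib_locate(query_seq, target)
            if loc is None:
                continue
            w_start = max(0, loc[0] - pad)
            w_end = min(len(target), loc[1] + pad)
            aln = local_align(query_seq, target[w_start:w_end], scoring)
            if aln.is_empty:
                continue
            t_start = w_start + aln.target_start
            t_end = w_start + aln.target_end
            if strand == "-":
                t_start, t_end = len(forward) - t_end, len(forward) - t_start
            candidate = AlignmentResult(
                score=aln.score, identity=aln.identity,
                n_aligned_columns=aln.n_aligned_columns,
                query_start=aln.query_start, query_end=aln.query_end,
                target_chrom=chrom, target_start=t_start, target_end=t_end,
                target_strand=strand,
            )
            if best is None or candidate.score > best.score:
                best = candidate
    if best is None:
        return None
    if best.identity < min_identity or best.n_aligned_columns < min_aligned:
        return None
    return best
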