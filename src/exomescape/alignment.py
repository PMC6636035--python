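"""Global protein alignment, percent identity and the divergence rule.

Ortholog pairs are aligned globally (Needleman–Wunsch with affine gaps,
BLOSUM62). Identity follows the gap-excluded definition

    identity = matching columns / (alignment length − gap columns)

so that incomplete sequence information (gap columns from truncated gene
models) lowers the denominator rather than the identity. Pairs under 30%
identity are discarded as unreliable orthology; divergence = 1 − identity
for the rest.

Gap scoring: a gap run of length L costs ``gap_open + (L−1)·gap_extend``;
defaults are the conventional protein settings open=12, extend=2.  The
unknown residue X scores 0 against everything and never counts as a match.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

DEFAULT_GAP_OPEN = 12.0
DEFAULT_GAP_EXTEND = 2.0
DEFAULT_MIN_IDENTITY = 0.30


@lru_cache(maxsize=None)
def blosum62_x_neutral():
    """BLOSUM62 with the X row/column zeroed (unknown residue is neutral)."""
    m = substitution_matrices.load("BLOSUM62").copy()
    x = m.alphabet.index("X")
    m[x, :] = 0.0
    m[:, x] = 0.0
    return m


@dataclass(frozen=True)
class AlignmentResult:
    """A global alignment and the identity derived from it."""

    aligned_a: str
    aligned_b: str
    score: float
    alignment_length: int
    match_count: int
    gap_columns: int
    identity: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")


def _make_aligner(matrix, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    # Biopython convention: first gap residue scores open, later ones extend.
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def _column_stats(a: str, b: str) -> tuple[int, int]:
    """(match_count, gap_columns): X never matches; a gap in either row
    makes a gap column."""
    matches = 0
    gaps = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            gaps += 1
        elif x == y and x != "X":
            matches += 1
    return matches, gaps


def global_align(
    a: str,
    b: str,
    matrix=None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> AlignmentResult:
    """Optimal global alignment of two protein sequences.

    Raises ``ValueError`` on empty input. The traceback is deterministic
    (the aligner's canonical first optimum).
    """
    if not a or not b:
        raise ValueError("global_align: empty sequence")
    if matrix is None:
        matrix = blosum62_x_neutral()
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    aln = aligner.align(a.upper(), b.upper())[0]
    ga, gb = str(aln[0]), str(aln[1])
    matches, gaps = _column_stats(ga, gb)
    length = len(ga)
    denom = length - gaps
    identity = matches / denom if denom > 0 else float("nan")
    return AlignmentResult(
        aligned_a=ga,
        aligned_b=gb,
        score=float(aln.score),
        alignment_length=length,
        match_count=matches,
        gap_columns=gaps,
        identity=identity,
    )


def percent_identity(aln: AlignmentResult) -> float:
    """Gap-excluded identity fraction of an alignment (NaN if all-gap)."""
    denom = aln.alignment_length - aln.gap_columns
    if denom <= 0:
        return float("nan")
    return aln.match_count / denom


def divergence(identity: float, threshold: float = DEFAULT_MIN_IDENTITY) -> float | None:
    """1 − identity, or None ("discarded") when identity < threshold."""
    if np.isnan(identity):
        return None
    if identity < threshold:
        return None
    return 1.0 - identity


def pairwise_divergence_track(
    proteins_a: dict[str, str],
    proteins_b: dict[str, str],
    genes,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    threshold: float = DEFAULT_MIN_IDENTITY,
) -> pd.Series:
    """Per-gene protein divergence between two species over a gene set.

    ``proteins_a``/``proteins_b`` map gene symbol → protein sequence.
    Genes missing a protein in either species, or whose identity falls
    below the discard threshold, get NaN.
    """
    symbols = list(genes.symbols) if hasattr(genes, "symbols") else list(genes)
    values = []
    for g in symbols:
        pa, pb = proteins_a.get(g), proteins_b.get(g)
        if not pa or not pb:
            values.append(np.nan)
            continue
        aln = global_align(pa, pb, gap_open=gap_open, gap_extend=gap_extend)
        d = divergence(aln.identity, threshold)
        values.append(np.nan if d is None else d)
    return pd.Series(values, index=symbols, name="divergence", dtype=float)
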