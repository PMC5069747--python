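"""Pairwise global alignment helpers shared by discovery and classification.

Protein alignments use BLOSUM62 with affine gaps (open 10, extend 1 in score
units); nucleotide alignments use a simple match/mismatch scheme.  Identity
is exact matches over aligned columns, terminal gaps excluded.
"""

from __future__ import annotations

from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices


@lru_cache(maxsize=None)
def protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    _free_end_gaps(aligner)
    return aligner


def _free_end_gaps(aligner: Align.PairwiseAligner) -> None:
    # terminal gaps are free so a short peptide can sit inside a longer one
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older attribute names
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0


@lru_cache(maxsize=None)
def nucleotide_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -3.0
    aligner.open_gap_score = -8.0
    aligner.extend_gap_score = -1.0
    _free_end_gaps(aligner)
    return aligner


def _sanitize_protein(seq: str) -> str:
    # BLOSUM62 lacks J/U/O; map them to X so the aligner accepts any input.
    table = str.maketrans({"J": "X", "U": "X", "O": "X"})
    return seq.upper().translate(table)


def align_pair(seq_a: str, seq_b: str, kind: str = "protein"):
    """Return the best global alignment of two sequences."""
    if kind == "protein":
        aligner = protein_aligner()
        seq_a, seq_b = _sanitize_protein(seq_a), _sanitize_protein(seq_b)
    else:
        aligner = nucleotide_aligner()
        seq_a, seq_b = seq_a.upper(), seq_b.upper()
    return next(iter(aligner.align(seq_a, seq_b)))


def aligned_columns(alignment) -> list[tuple[str, str]]:
    """Expand an alignment into per-column (residue_a, residue_b) pairs.

    Gaps appear as '-'.  Columns are in alignment order and include terminal
    gap columns.
    """
    a_str, b_str = alignment[0], alignment[1]
    return list(zip(a_str, b_str))


def identity(alignment) -> float:
    """Fraction of exact matches over aligned columns, terminal gaps excluded."""
    cols = aligned_columns(alignment)
    # trim terminal gap columns (either row gapped at the ends)
    first = 0
    last = len(cols)
    while first < last and "-" in cols[first]:
        first += 1
    while last > first and "-" in cols[last - 1]:
        last -= 1
    core = cols[first:last]
    if not core:
        return 0.0
    matches = sum(1 for a, b in core if a == b and a != "-")
    return matches / len(core)


def identity_global(alignment) -> float:
    """Fraction of exact matches over ALL aligned columns (terminal gaps count).

    This is the coverage-sensitive identity used for role calling: a short
    fragment matching perfectly over a tenth of the reference scores ~0.1,
    not 1.0.
    """
    cols = aligned_columns(alignment)
    if not cols:
        return 0.0
    matches = sum(1 for a, b in cols if a == b and a != "-")
    return matches / len(cols)


def pairwise_identity(seq_a: str, seq_b: str, kind: str = "protein") -> float:
    """Global-alignment identity (terminal gaps excluded) between two sequences."""
    return identity(align_pair(seq_a, seq_b, kind))


def pairwise_identity_global(seq_a: str, seq_b: str, kind: str = "protein") -> float:
    """Global-alignment identity over all columns between two sequences."""
    return identity_global(align_pair(seq_a, seq_b, kind))
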