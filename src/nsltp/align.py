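"""Shared pairwise global-alignment helpers (Biopython PairwiseAligner)."""

from __future__ import annotations

from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices


@lru_cache(maxsize=None)
def _nuc_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -5
    a.extend_gap_score = -1
    return a


@lru_cache(maxsize=None)
def _prot_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -10
    a.extend_gap_score = -1
    return a


def _gapped_rows(alignment) -> tuple[str, str]:
    return str(alignment[0]), str(alignment[1])


def _trim_terminal_gaps(ga: str, gb: str) -> tuple[str, str]:
    lead = max(_leading_gap(ga), _leading_gap(gb))
    trail = max(_leading_gap(ga[::-1]), _leading_gap(gb[::-1]))
    end = len(ga) - trail
    return ga[lead:end], gb[lead:end]


def _leading_gap(s: str) -> int:
    n = 0
    for ch in s:
        if ch != "-":
            break
        n += 1
    return n


def align_global_nuc(a: str, b: str):
    """Best global nucleotide alignment as a pair of gapped strings."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aln = _nuc_aligner().align(a, b)[0]
    return _gapped_rows(aln)


def align_global_protein(a: str, b: str):
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aln = _prot_aligner().align(a, b)[0]
    return _gapped_rows(aln)


def protein_identity(a: str, b: str) -> float:
    """Fraction of identical residues over aligned columns, excluding
    terminal gap columns."""
    ga, gb = align_global_protein(a, b)
    ga, gb = _trim_terminal_gaps(ga, gb)
    cols = sum(1 for x, y in zip(ga, gb) if not (x == "-" and y == "-"))
    matches = sum(1 for x, y in zip(ga, gb) if x == y and x != "-")
    return matches / cols if cols else 0.0
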