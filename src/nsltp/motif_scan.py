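"""Eight-cysteine-motif (8CM) detection and spacing analysis.

The nsLTP family is defined by the conserved backbone
``C-Xn-C-Xn-CC-Xn-CXC-Xn-C-Xn-C``: eight cysteines with two fixed anchors
(the adjacent CC pair and the CXC triplet) and five variable inter-cysteine
gaps g1..g5. The scanner enumerates cysteine 8-tuples satisfying the
anchors and per-gap bounds, then resolves overlaps deterministically.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .core_io import SequenceRecord, six_frame_translate

#: residues counted as hydrophobic for CXC polarity
HYDROPHOBIC = frozenset("AVLIMFWCPG")

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class GapBounds:
    """Inclusive (min, max) bounds for the five variable 8CM gaps.

    The defaults are the union of the wheat per-type spacing ranges with a
    small margin on each maximum, so every printed wheat spacing is covered;
    they are fully user-configurable.
    """

    g1: tuple[int, int] = (3, 21)
    g2: tuple[int, int] = (8, 29)
    g3: tuple[int, int] = (8, 23)
    g4: tuple[int, int] = (8, 38)
    g5: tuple[int, int] = (3, 22)

    def __post_init__(self):
        for lo, hi in self.as_tuple():
            if lo < 1 or lo > hi:
                raise ValueError(f"bad gap bound ({lo},{hi})")

    def as_tuple(self):
        return (self.g1, self.g2, self.g3, self.g4, self.g5)


DEFAULT_GAP_BOUNDS = GapBounds()


@dataclass(frozen=True)
class EightCMMatch:
    """One 8CM occurrence: cysteine indices, gap vector and the CXC X residue.

    ``cys_positions`` are 0-based indices into the scanned peptide. Gaps are
    residue counts between consecutive motif cysteines: g1=C1->C2, g2=C2->C3,
    g3=C4->C5, g4=C6->C7, g5=C7->C8 (C3C4 are the adjacent CC; exactly one
    residue sits between C5 and C6).
    """

    sequence_id: str
    cys_positions: tuple[int, ...]
    gaps: tuple[int, int, int, int, int]
    cxc_x_residue: str
    frame: str | None = None

    def __post_init__(self):
        p = self.cys_positions
        if len(p) != 8 or any(b <= a for a, b in zip(p, p[1:])):
            raise ValueError("cys_positions must be 8 strictly increasing indices")
        if p[3] != p[2] + 1:
            raise ValueError("C3 and C4 must be adjacent (CC anchor)")
        if p[5] != p[4] + 2:
            raise ValueError("exactly one residue must separate C5 and C6 (CXC anchor)")
        expect = (p[1] - p[0] - 1, p[2] - p[1] - 1, p[4] - p[3] - 1,
                  p[6] - p[5] - 1, p[7] - p[6] - 1)
        if expect != self.gaps:
            raise ValueError(f"gaps {self.gaps} inconsistent with positions (expect {expect})")

    @property
    def start(self) -> int:
        return self.cys_positions[0]

    @property
    def end(self) -> int:
        """Exclusive end of the motif span."""
        return self.cys_positions[7] + 1

    @property
    def span(self) -> int:
        return self.end - self.start


def _candidates(seq: str, bounds: GapBounds):
    """All cysteine 8-tuples satisfying the anchors and gap bounds."""
    cys = [i for i, r in enumerate(seq) if r == "C"]
    cset = set(cys)
    (l1, h1), (l2, h2), (l3, h3), (l4, h4), (l5, h5) = bounds.as_tuple()
    out = []
    for p1 in cys:
        for p2 in cys:
            g1 = p2 - p1 - 1
            if g1 < l1:
                continue
            if g1 > h1:
                break
            for p3 in cys:
                g2 = p3 - p2 - 1
                if g2 < l2:
                    continue
                if g2 > h2:
                    break
                p4 = p3 + 1
                if p4 not in cset:
                    continue
                for p5 in cys:
                    g3 = p5 - p4 - 1
                    if g3 < l3:
                        continue
                    if g3 > h3:
                        break
                    p6 = p5 + 2
                    if p6 not in cset:
                        continue
                    for p7 in cys:
                        g4 = p7 - p6 - 1
                        if g4 < l4:
                            continue
                        if g4 > h4:
                            break
                        for p8 in cys:
                            g5 = p8 - p7 - 1
                            if g5 < l5:
                                continue
                            if g5 > h5:
                                break
                            out.append((p1, p2, p3, p4, p5, p6, p7, p8))
    return out


def scan_eight_cm(
    protein: SequenceRecord,
    bounds: GapBounds = DEFAULT_GAP_BOUNDS,
    all_candidates: bool = False,
    frame: str | None = None,
) -> list[EightCMMatch]:
    """Find 8CM occurrences in a protein.

    Candidates are ordered by (start, span, positions); unless
    ``all_candidates`` is set, overlapping candidates are resolved greedily
    by leftmost start then smallest total span, yielding a deterministic,
    non-overlapping set of matches.
    """
    if protein.alphabet != "protein":
        raise ValueError("scan_eight_cm requires a protein record")
    seq = protein.residues
    tuples = sorted(_candidates(seq, bounds), key=lambda p: (p[0], p[7] - p[0], p))
    chosen = []
    last_end = -1
    for p in tuples:
        if not all_candidates:
            if p[0] <= last_end:
                continue
            last_end = p[7]
        gaps = (p[1] - p[0] - 1, p[2] - p[1] - 1, p[4] - p[3] - 1,
                p[6] - p[5] - 1, p[7] - p[6] - 1)
        chosen.append(
            EightCMMatch(protein.id, p, gaps, seq[p[4] + 1], frame=frame)
        )
    return chosen


def scan_dna_six_frames(
    record: SequenceRecord, bounds: GapBounds = DEFAULT_GAP_BOUNDS
) -> list[EightCMMatch]:
    """Scan all six conceptual translations of a DNA sequence for the 8CM."""
    matches = []
    for frame, pep in six_frame_translate(record).items():
        if not pep:
            continue
        prot = SequenceRecord.protein(record.id, pep)
        matches.extend(scan_eight_cm(prot, bounds, frame=frame))
    return matches


# ---------------------------------------------------------------------------
# spacing signatures
# ---------------------------------------------------------------------------

@dataclass
class SpacingSignature:
    """Per-type multiset of observed gap values, renderable in CXn notation."""

    type_label: str
    gap_values: tuple[Counter, ...]  # five Counters
    unique_values: tuple[frozenset, ...] = field(
        default_factory=lambda: tuple(frozenset() for _ in range(5))
    )

    def render(self) -> str:
        if all(not c for c in self.gap_values):
            return ""
        segs = [_render_values(sorted(c)) for c in self.gap_values]
        return (f"CX{segs[0]}CX{segs[1]}CCX{segs[2]}CXCX{segs[3]}CX{segs[4]}C")


def _render_values(values: list[int]) -> str:
    """Collapse sorted integers to the compact range notation used in print."""
    if not values:
        return ""
    runs, start, prev = [], values[0], values[0]
    for v in values[1:]:
        if v == prev + 1:
            prev = v
            continue
        runs.append((start, prev))
        start = prev = v
    runs.append((start, prev))
    return ",".join(f"{a}" if a == b else f"{a}-{b}" for a, b in runs)


def spacing_signature(
    matches_by_type: dict[str, list[EightCMMatch]]
) -> dict[str, SpacingSignature]:
    """Summarize gap-value multisets per type and flag type-unique values."""
    sigs = {}
    for label, matches in matches_by_type.items():
        counters = tuple(Counter(m.gaps[g] for m in matches) for g in range(5))
        sigs[label] = SpacingSignature(label, counters)
    for g in range(5):
        for label, sig in sigs.items():
            others = set()
            for olabel, osig in sigs.items():
                if olabel != label:
                    others |= set(osig.gap_values[g])
            uniq = frozenset(set(sig.gap_values[g]) - others)
            lst = list(sig.unique_values)
            lst[g] = uniq
            sig.unique_values = tuple(lst)
    return sigs


def cxc_polarity(matches_by_type: dict[str, list[EightCMMatch]]) -> dict[str, float]:
    """Fraction of matches per type whose CXC X residue is hydrophobic.

    Unknown residues (X) are excluded from the denominator.
    """
    import logging

    out = {}
    for label, matches in matches_by_type.items():
        known = [m for m in matches if m.cxc_x_residue != "X"]
        if len(known) < len(matches):
            logging.getLogger(__name__).warning(
                "%s: %d matches with unknown CXC residue excluded",
                label, len(matches) - len(known),
            )
        out[label] = (
            sum(m.cxc_x_residue in HYDROPHOBIC for m in known) / len(known)
            if known else float("nan")
        )
    return out


# ---------------------------------------------------------------------------
# position-count (logo) matrices
# ---------------------------------------------------------------------------

@dataclass
class PositionCountMatrix:
    """Aligned 8CM columns x 20 residues -> counts, exportable for logo tools."""

    columns: list[str]
    counts: np.ndarray  # shape (n_columns, 20), order AA20

    def to_tsv(self) -> str:
        header = "column\t" + "\t".join(AA20)
        lines = [header]
        for label, row in zip(self.columns, self.counts):
            lines.append(label + "\t" + "\t".join(str(int(v)) for v in row))
        return "\n".join(lines) + "\n"


def position_counts(
    matches: list[EightCMMatch], proteins: dict[str, str]
) -> PositionCountMatrix:
    """Count residues per aligned motif column over a set of matches.

    Columns are the 8 cysteines plus per-gap blocks padded to the maximum
    observed gap; shorter gaps are left-aligned within their block, so a gap
    column's sum equals the number of sequences whose gap covers it.
    """
    if not matches:
        return PositionCountMatrix([], np.zeros((0, 20), dtype=int))
    max_gap = [max(m.gaps[g] for m in matches) for g in range(5)]
    columns: list[str] = []
    layout: list[tuple[str, int]] = []  # (kind, index) kind: C1..C8 or gN.j
    for cname, gidx in (("C1", 0), ("C2", 1)):
        columns.append(cname)
        layout.append(("cys", int(cname[1]) - 1))
        for j in range(max_gap[gidx]):
            columns.append(f"g{gidx + 1}.{j + 1}")
            layout.append((f"gap{gidx}", j))
    columns += ["C3", "C4"]
    layout += [("cys", 2), ("cys", 3)]
    for j in range(max_gap[2]):
        columns.append(f"g3.{j + 1}")
        layout.append(("gap2", j))
    columns += ["C5", "X", "C6"]
    layout += [("cys", 4), ("cxc_x", 0), ("cys", 5)]
    for j in range(max_gap[3]):
        columns.append(f"g4.{j + 1}")
        layout.append(("gap3", j))
    columns.append("C7")
    layout.append(("cys", 6))
    for j in range(max_gap[4]):
        columns.append(f"g5.{j + 1}")
        layout.append(("gap4", j))
    columns.append("C8")
    layout.append(("cys", 7))

    aa_index = {a: i for i, a in enumerate(AA20)}
    counts = np.zeros((len(columns), 20), dtype=int)
    for m in matches:
        seq = proteins[m.sequence_id]
        p = m.cys_positions
        for col, (kind, j) in enumerate(layout):
            if kind == "cys":
                res = seq[p[j]]
            elif kind == "cxc_x":
                res = m.cxc_x_residue
            else:
                g = int(kind[3])
                if j >= m.gaps[g]:
                    continue
                left_cys = {0: 0, 1: 1, 2: 3, 3: 5, 4: 6}[g]
                res = seq[p[left_cys] + 1 + j]
            if res in aa_index:
                counts[col, aa_index[res]] += 1
    return PositionCountMatrix(columns, counts)
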