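"""Mature-protein derivation and five-type nsLTP classification.

Types follow the intron/GPI-based system used for plant nsLTPs:

* type G — carries a GPI omega-site (any intron count, up to four seen);
* type 2 — no intron within or downstream of the 8CM region;
* types 1 / C / D — a single intron placed respectively 5, 1 and 4
  nucleotides after the last base of the last 8CM cysteine codon;
* a single downstream intron at any other offset can still be called
  type 2 when the mature peptide is sufficiently similar to curated
  intronless type-2 members (identity override);
* everything else is unassigned.

Intron offsets are measured in CDS coordinates from the last base of the
last 8CM cysteine codon to the first intron base (offset 1 = the intron
starts immediately after that codon).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .align import protein_identity
from .core_io import GeneModel, GenomicInterval, MaturationAnnotation, SequenceRecord
from .motif_scan import EightCMMatch, GapBounds, DEFAULT_GAP_BOUNDS, scan_eight_cm

log = logging.getLogger(__name__)

TYPES = ("type1", "type2", "typeC", "typeD", "typeG", "unassigned")

#: single-intron offset -> type, for the diagnostic intron placements
_OFFSET_TO_TYPE = {5: "type1", 1: "typeC", 4: "typeD"}

_HYDROPHOBIC = frozenset("AVLIMFWCPG")


@dataclass
class LTPRecord:
    """One classified family member with all derived attributes."""

    gene_id: str
    type: str = "unassigned"
    mature_sequence: str = ""
    match: EightCMMatch | None = None
    gpi: bool = False
    intron_offsets: list[int] = field(default_factory=list)
    hyprp: bool = False
    mw_da: float | None = None
    pi: float | None = None
    location: GenomicInterval | None = None
    flags: list[str] = field(default_factory=list)


def derive_mature_protein(protein: str, annotation: MaturationAnnotation) -> str:
    """Strip the signal peptide and, when present, the GPI pro-peptide.

    Residues 1..signal_cleavage and residues beyond the omega-site are
    removed (1-based annotation positions). Candidates with no signal
    peptide at all are excluded upstream of this call.
    """
    if annotation.signal_cleavage >= len(protein):
        raise ValueError(
            f"{annotation.protein_id}: cleavage {annotation.signal_cleavage} "
            f">= protein length {len(protein)}"
        )
    if annotation.gpi_omega > len(protein):
        raise ValueError(f"{annotation.protein_id}: omega-site beyond protein end")
    end = annotation.gpi_omega if annotation.gpi_omega else len(protein)
    return protein[annotation.signal_cleavage : end]


def heuristic_maturation(protein: str, c1_index: int | None = None) -> MaturationAnnotation:
    """Hydrophobicity-window stand-in for an external signal-peptide call.

    The longest 16-30 residue N-terminal window with >=70% hydrophobic
    residues (ending before the first motif cysteine when known) is taken
    as the signal peptide. Returns cleavage 0 when no window qualifies.
    """
    limit = min(30, len(protein) - 1, (c1_index or len(protein)) - 1)
    best = 0
    for length in range(16, limit + 1):
        window = protein[:length]
        if sum(r in _HYDROPHOBIC for r in window) / length >= 0.70:
            best = length
    return MaturationAnnotation(protein_id="", signal_cleavage=best, source="heuristic")


def intron_offsets_from_model(gene: GeneModel, last_cys_cds_end: int) -> list[int]:
    """Offsets of CDS-interrupting introns relative to the last 8CM cysteine
    codon (first intron base minus last codon base, in CDS coordinates)."""
    return [prefix - last_cys_cds_end for prefix in gene.cds_intron_prefixes()]


def classify_type(
    gpi: bool,
    intron_offsets: list[int],
    mature_sequence: str = "",
    reference_type2: list[str] = (),
    motif_span_nt: int = 0,
    identity_override: float = 0.60,
) -> str:
    """Assign one of the five types (or unassigned) from GPI status and
    intron architecture, with a sequence-identity fallback to type 2.

    ``intron_offsets`` are relative to the last base of the last 8CM
    cysteine codon; ``motif_span_nt`` (the 8CM length in CDS nucleotides)
    separates introns upstream of the motif from those within/after it.
    """
    if gpi:
        return "typeG"
    # introns strictly 5' of the 8CM region are not diagnostic
    relevant = [o for o in intron_offsets if o > 1 - motif_span_nt]
    if not relevant:
        return "type2"
    if len(relevant) == 1:
        off = relevant[0]
        if off in _OFFSET_TO_TYPE:
            return _OFFSET_TO_TYPE[off]
        if off >= 1 and mature_sequence and reference_type2:
            best = max(protein_identity(mature_sequence, ref) for ref in reference_type2)
            if best >= identity_override:
                return "type2"
    return "unassigned"


def flag_hyprp(
    mature_sequence: str,
    match: EightCMMatch,
    min_len: int = 15,
    p_frac: float = 0.20,
) -> bool:
    """Proline-rich (HyPRP-like) flag: the region from the mature N-terminus
    to C1 is at least ``min_len`` residues with proline fraction >= ``p_frac``."""
    region = mature_sequence[: match.cys_positions[0]]
    if len(region) < min_len:
        return False
    return region.count("P") / len(region) >= p_frac


def summarize_family(records: list[LTPRecord]):
    """Per-type counts and percentages plus the unique-mature-protein count.

    Percentages are 100*count/total rounded to 2 decimals; uniqueness is by
    exact mature-sequence string.
    """
    import pandas as pd

    counts = {t: 0 for t in TYPES}
    for rec in records:
        counts[rec.type] += 1
    total = len(records)
    table = pd.DataFrame(
        {
            "type": list(counts),
            "count": list(counts.values()),
            "percent": [
                round(100 * c / total, 2) if total else 0.0 for c in counts.values()
            ],
        }
    )
    unique = len({rec.mature_sequence for rec in records if rec.mature_sequence})
    return {"table": table, "total": total, "unique_mature": unique}


# ---------------------------------------------------------------------------
# record assembly (two passes: structural rules, then identity override)
# ---------------------------------------------------------------------------

def build_ltp_records(
    genes: list[GeneModel],
    proteins: dict[str, str],
    annotations: dict[str, MaturationAnnotation],
    bounds: GapBounds = DEFAULT_GAP_BOUNDS,
    identity_override: float = 0.60,
    deny_list: set[str] = frozenset(),
    compute_physchem: bool = True,
) -> list[LTPRecord]:
    """Classify a candidate set end to end.

    Candidates without an annotation fall back to the hydrophobicity
    heuristic; candidates with no signal peptide, no 8CM in the mature
    peptide, or on the user deny-list are dropped (with a log line). The
    identity override to type 2 uses the structurally-called intronless
    type-2 members as the reference set.
    """
    from . import physchem

    records: list[LTPRecord] = []
    deferred: list[tuple[LTPRecord, list[int], int]] = []

    for gene in genes:
        gid = gene.gene_id
        if gid in deny_list:
            log.info("%s: on deny-list, excluded", gid)
            continue
        protein = proteins[gid]
        ann = annotations.get(gid)
        if ann is None:
            full_matches = scan_eight_cm(SequenceRecord.protein(gid, protein), bounds)
            c1 = full_matches[0].cys_positions[0] if full_matches else None
            ann = heuristic_maturation(protein, c1)
            ann = MaturationAnnotation(gid, ann.signal_cleavage, 0, "heuristic")
        if ann.signal_cleavage == 0:
            log.info("%s: no signal peptide, excluded", gid)
            continue
        mature = derive_mature_protein(protein, ann)
        matches = scan_eight_cm(SequenceRecord.protein(gid, mature), bounds)
        if not matches:
            log.info("%s: no 8CM in mature peptide, excluded", gid)
            continue
        rec = LTPRecord(
            gene_id=gid,
            mature_sequence=mature,
            match=matches[0],
            gpi=ann.gpi_omega > 0,
            location=gene.location,
        )
        if ann.source == "heuristic":
            rec.flags.append("maturation:heuristic")
        if len(matches) > 1:
            rec.flags.append("multiple_8cm")
            rec.type = "unassigned"
            records.append(rec)
            continue
        m = matches[0]
        # CDS coordinate of the last base of the C8 codon, in full-protein frame
        c8_full = m.cys_positions[7] + ann.signal_cleavage
        last_cys_cds_end = 3 * c8_full + 2
        c1_full = m.cys_positions[0] + ann.signal_cleavage
        motif_span_nt = last_cys_cds_end - 3 * c1_full + 1
        rec.intron_offsets = intron_offsets_from_model(gene, last_cys_cds_end)
        rec.type = classify_type(
            rec.gpi, rec.intron_offsets, motif_span_nt=motif_span_nt
        )
        rec.hyprp = flag_hyprp(mature, m)
        if compute_physchem and not (set(mature) - set(physchem.DEFAULT_MASSES.residue_mass)):
            rec.mw_da = physchem.molecular_weight(mature)
            rec.pi = physchem.isoelectric_point(mature)
        if rec.type == "unassigned" and len(
            [o for o in rec.intron_offsets if o > 1 - motif_span_nt]
        ) == 1:
            deferred.append((rec, rec.intron_offsets, motif_span_nt))
        records.append(rec)

    reference = [r.mature_sequence for r in records if r.type == "type2"]
    for rec, offsets, span in deferred:
        rec.type = classify_type(
            rec.gpi, offsets, rec.mature_sequence, reference, span, identity_override
        )
    return records
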