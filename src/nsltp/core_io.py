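"""Sequence containers, coordinate conventions and standard-format I/O.

All internal coordinates are 0-based half-open. GFF3 (1-based inclusive)
and BED (0-based half-open) are converted only at the I/O boundary so that
no off-by-one arithmetic leaks into the analysis modules.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Data import CodonTable

log = logging.getLogger(__name__)

DNA_ALPHABET = set("ACGTN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X", "*"}

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
#: codon -> one-letter residue, with stop codons rendered '*'
CODON_TO_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
for _stop in _STANDARD_TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FRAMES = ("+1", "+2", "+3", "-1", "-2", "-3")


class Gff3ParseError(ValueError):
    """Raised on malformed GFF3 input; the message names the offending line."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence over the DNA or protein alphabet (upper-cased on ingest)."""

    id: str
    residues: str
    alphabet: str  # "dna" | "protein"

    def __post_init__(self):
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.residues:
            raise ValueError(f"{self.id}: empty sequence")
        if self.alphabet == "dna":
            bad = set(self.residues) - DNA_ALPHABET
        elif self.alphabet == "protein":
            bad = set(self.residues) - PROTEIN_ALPHABET
        else:
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        if bad:
            raise ValueError(
                f"{self.id}: residues {sorted(bad)} not allowed in {self.alphabet}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @classmethod
    def dna(cls, id: str, residues: str) -> "SequenceRecord":
        return cls(id, residues, "dna")

    @classmethod
    def protein(cls, id: str, residues: str) -> "SequenceRecord":
        return cls(id, residues, "protein")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a named chromosome/contig."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    """One transcript (mRNA) with its exon and CDS structure."""

    gene_id: str
    location: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    cds_exons: list[GenomicInterval] = field(default_factory=list)
    parent_gene: str | None = None

    def __post_init__(self):
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        self.cds_exons = sorted(self.cds_exons, key=lambda iv: iv.start)
        for prev, nxt in zip(self.exons, self.exons[1:]):
            if nxt.start < prev.end:
                raise ValueError(f"{self.gene_id}: overlapping exons")

    @property
    def strand(self) -> str:
        return self.location.strand

    @property
    def introns(self) -> list[GenomicInterval]:
        """Gaps between consecutive exons, in genomic order."""
        out = []
        for prev, nxt in zip(self.exons, self.exons[1:]):
            if nxt.start > prev.end:
                out.append(
                    GenomicInterval(self.location.chrom, prev.end, nxt.start, self.strand)
                )
        return out

    @property
    def cds_length(self) -> int:
        return sum(len(iv) for iv in self.cds_exons)

    def cds_intron_prefixes(self) -> list[int]:
        """Number of CDS bases 5' of each intron that interrupts the CDS."""
        exons = self.cds_exons if self.strand == "+" else list(reversed(self.cds_exons))
        prefixes, total = [], 0
        for iv in exons[:-1]:
            total += len(iv)
            prefixes.append(total)
        return prefixes


@dataclass(frozen=True)
class MaturationAnnotation:
    """Signal-peptide cleavage site and GPI omega-site for one protein.

    Positions are 1-based residue counts; 0 means "absent". These normally
    come from external predictor tables; ``source`` records whether the call
    came from such a table or from the in-package hydrophobicity heuristic.
    """

    protein_id: str
    signal_cleavage: int = 0
    gpi_omega: int = 0
    source: str = "external_table"

    def __post_init__(self):
        if self.signal_cleavage < 0 or self.gpi_omega < 0:
            raise ValueError(f"{self.protein_id}: negative maturation position")
        if self.signal_cleavage and self.gpi_omega:
            if not self.signal_cleavage < self.gpi_omega:
                raise ValueError(
                    f"{self.protein_id}: cleavage {self.signal_cleavage} "
                    f"not before omega-site {self.gpi_omega}"
                )


# ---------------------------------------------------------------------------
# translation
# ---------------------------------------------------------------------------

def translate(dna: str) -> str:
    """Translate one reading frame; codons containing N become X, stops '*'.

    Trailing partial codons are dropped.
    """
    out = []
    for i in range(0, len(dna) - len(dna) % 3, 3):
        codon = dna[i : i + 3]
        out.append(CODON_TO_AA.get(codon, "X"))
    return "".join(out)


def six_frame_translate(record: SequenceRecord) -> dict[str, str]:
    """All six conceptual translations of a DNA record, keyed by frame label."""
    if record.alphabet != "dna":
        raise ValueError("six_frame_translate requires a DNA record")
    fwd, rev = record.residues, reverse_complement(record.residues)
    return {
        "+1": translate(fwd),
        "+2": translate(fwd[1:]),
        "+3": translate(fwd[2:]),
        "-1": translate(rev),
        "-2": translate(rev[1:]),
        "-3": translate(rev[2:]),
    }


def extract_spliced_cds(gene: GeneModel, genome: dict[str, str] | SequenceRecord) -> SequenceRecord:
    """Concatenate a gene's CDS exons 5'->3' (minus strand reverse-complemented)."""
    if isinstance(genome, SequenceRecord):
        genome = {genome.id: genome.residues}
    chrom = gene.location.chrom
    if chrom not in genome:
        raise KeyError(f"{gene.gene_id}: chromosome {chrom} absent from genome")
    seq = genome[chrom]
    parts = []
    for iv in gene.cds_exons:
        if iv.end > len(seq):
            raise IndexError(f"{gene.gene_id}: exon {iv} beyond end of {chrom}")
        parts.append(seq[iv.start : iv.end])
    cds = "".join(parts)
    if gene.strand == "-":
        cds = reverse_complement(cds)
    return SequenceRecord.dna(gene.gene_id, cds)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path_or_handle, alphabet: str = "dna") -> list[SequenceRecord]:
    records = []
    for rec in SeqIO.parse(path_or_handle, "fasta"):
        records.append(SequenceRecord(rec.id, str(rec.seq), alphabet))
    return records


def write_fasta(records: list[SequenceRecord], handle_or_path, width: int = 60) -> None:
    own = isinstance(handle_or_path, (str, bytes)) or hasattr(handle_or_path, "__fspath__")
    fh = open(handle_or_path, "w") if own else handle_or_path
    try:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")
    finally:
        if own:
            fh.close()


# ---------------------------------------------------------------------------
# GFF3 (gene/mRNA/exon/CDS subset)
# ---------------------------------------------------------------------------

def _parse_attributes(col: str) -> dict[str, str]:
    out = {}
    for part in col.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def parse_gff3_gene_models(gff3_text: str) -> list[GeneModel]:
    """Parse the gene/mRNA/exon/CDS subset of GFF3 into gene models.

    1-based inclusive GFF3 coordinates become 0-based half-open. One
    GeneModel is produced per mRNA; ordering is deterministic by
    (chrom, start, gene_id). mRNAs whose spliced CDS length is not a
    multiple of 3 are excluded with a warning. A CDS or exon whose Parent
    mRNA is never declared raises Gff3ParseError naming the line.
    """
    mrnas: dict[str, tuple[GenomicInterval, str]] = {}
    children: dict[str, dict[str, list[GenomicInterval]]] = {}
    pending: list[tuple[int, str, str, GenomicInterval]] = []

    for lineno, line in enumerate(io.StringIO(gff3_text), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise Gff3ParseError(f"line {lineno}: expected 9 columns, got {len(cols)}")
        chrom, _src, ftype, start, end, _score, strand, _phase, attrs = cols
        if ftype not in ("gene", "mRNA", "exon", "CDS"):
            continue
        try:
            iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
        except ValueError as exc:
            raise Gff3ParseError(f"line {lineno}: {exc}") from None
        att = _parse_attributes(attrs)
        if ftype == "mRNA":
            mid = att.get("ID")
            if mid is None:
                raise Gff3ParseError(f"line {lineno}: mRNA without ID")
            mrnas[mid] = (iv, att.get("Parent", mid))
            children.setdefault(mid, {"exon": [], "CDS": []})
        elif ftype in ("exon", "CDS"):
            parent = att.get("Parent")
            if parent is None:
                raise Gff3ParseError(f"line {lineno}: {ftype} without Parent")
            pending.append((lineno, ftype, parent, iv))

    models = []
    for lineno, ftype, parent, iv in pending:
        if parent not in children:
            raise Gff3ParseError(
                f"line {lineno}: {ftype} references undeclared parent mRNA {parent!r}"
            )
        children[parent][ftype].append(iv)

    for mid, (iv, _gene) in mrnas.items():
        exons = children[mid]["exon"] or children[mid]["CDS"]
        cds = children[mid]["CDS"]
        model = GeneModel(mid, iv, exons, cds, parent_gene=_gene)
        if model.cds_length % 3 != 0:
            log.warning("%s: CDS length %d not divisible by 3; excluded", mid, model.cds_length)
            continue
        models.append(model)
    models.sort(key=lambda m: (m.location.chrom, m.location.start, m.gene_id))
    return models


def write_gff3(models: list[GeneModel], gene_parents: dict[str, str] | None = None) -> str:
    """Serialize gene models back to GFF3 (gene + mRNA + exon + CDS rows)."""
    lines = ["##gff-version 3"]
    for m in sorted(models, key=lambda m: (m.location.chrom, m.location.start, m.gene_id)):
        loc = m.location
        gene_id = (gene_parents or {}).get(m.gene_id, m.gene_id + ".gene")
        base = f"{loc.chrom}\tnsltp\t"
        tail = f"\t.\t{loc.strand}\t.\t"
        lines.append(base + f"gene\t{loc.start + 1}\t{loc.end}" + tail + f"ID={gene_id}")
        lines.append(
            base + f"mRNA\t{loc.start + 1}\t{loc.end}" + tail
            + f"ID={m.gene_id};Parent={gene_id}"
        )
        for iv in m.exons:
            lines.append(base + f"exon\t{iv.start + 1}\t{iv.end}" + tail + f"Parent={m.gene_id}")
        for iv in m.cds_exons:
            lines.append(
                f"{loc.chrom}\tnsltp\tCDS\t{iv.start + 1}\t{iv.end}\t.\t{loc.strand}\t0\t"
                f"Parent={m.gene_id}"
            )
    return "\n".join(lines) + "\n"


def select_longest_cds(
    models: list[GeneModel], gene_of: dict[str, str] | None = None
) -> list[GeneModel]:
    """Keep one mRNA per gene: the longest CDS (ties broken by mRNA id)."""
    best: dict[str, GeneModel] = {}
    for m in models:
        g = (gene_of or {}).get(m.gene_id) or m.parent_gene or m.gene_id
        cur = best.get(g)
        if cur is None or (m.cds_length, m.gene_id) > (cur.cds_length, cur.gene_id):
            best[g] = m
    return sorted(best.values(), key=lambda m: (m.location.chrom, m.location.start, m.gene_id))


# ---------------------------------------------------------------------------
# chromosome map / BED export
# ---------------------------------------------------------------------------

def export_chromosome_map(records, chrom_lengths: dict[str, int] | None = None):
    """BED6 text plus a per-chromosome gene-density table.

    ``records`` is any iterable of objects with ``gene_id`` and ``location``
    attributes (LTPRecord in the pipeline). Records without a location are
    skipped with a warning, mirroring family members that cannot be placed
    on the assembly. Density is genes per Mbp when chromosome lengths are
    supplied.
    """
    import pandas as pd

    rows = []
    for rec in records:
        loc = getattr(rec, "location", None)
        if loc is None:
            log.warning("%s: no genomic location; omitted from chromosome map", rec.gene_id)
            continue
        rows.append((loc.chrom, loc.start, loc.end, rec.gene_id, 0, loc.strand))
    rows.sort(key=lambda r: (r[0], r[1], r[3]))
    bed = "".join("\t".join(map(str, r)) + "\n" for r in rows)

    counts: dict[str, int] = {}
    for r in rows:
        counts[r[0]] = counts.get(r[0], 0) + 1
    table = pd.DataFrame(
        {"chrom": sorted(counts), "n_genes": [counts[c] for c in sorted(counts)]}
    )
    if chrom_lengths and not table.empty:
        table["length_mbp"] = [chrom_lengths.get(c, float("nan")) / 1e6 for c in table["chrom"]]
        table["genes_per_mbp"] = table["n_genes"] / table["length_mbp"]
    return bed, table


def write_maturation_tsv(annotations: list[MaturationAnnotation]) -> str:
    lines = ["protein_id\tsignal_cleavage\tgpi_omega\tsource"]
    for a in annotations:
        lines.append(f"{a.protein_id}\t{a.signal_cleavage}\t{a.gpi_omega}\t{a.source}")
    return "\n".join(lines) + "\n"


def read_maturation_tsv(text: str) -> dict[str, MaturationAnnotation]:
    out = {}
    for line in text.splitlines()[1:]:
        if not line.strip() or line.startswith("#"):
            continue
        pid, cleav, omega, source = line.split("\t")[:4]
        out[pid] = MaturationAnnotation(pid, int(cleav), int(omega), source)
    return out


def parse_bed6(text: str) -> list[tuple[str, GenomicInterval]]:
    out = []
    for line in text.splitlines():
        if not line.strip():
            continue
        chrom, start, end, name, _score, strand = line.split("\t")[:6]
        out.append((name, GenomicInterval(chrom, int(start), int(end), strand)))
    return out
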