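"""Synthetic genomes, expression matrices and promoter sets with recorded
ground truth.

Every generator is a pure function of (config, seed): the same inputs give
byte-identical outputs. The genome generator plants nsLTP genes with
type-specific 8CM spacings and intron placements, tandem arrays derived
from a common seed CDS by controlled synonymous/non-synonymous mutation,
and cysteine-free intergenic background, so the planted motifs are the
only 8CM instances and every downstream stage can be scored against truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    CODON_TO_AA,
    GeneModel,
    GenomicInterval,
    MaturationAnnotation,
    SequenceRecord,
    reverse_complement,
)

# ---------------------------------------------------------------------------
# type-specific spacing table (allowed gap values per type, g1..g5)
# ---------------------------------------------------------------------------

def _vals(*items):
    out = set()
    for it in items:
        if isinstance(it, tuple):
            out.update(range(it[0], it[1] + 1))
        else:
            out.add(it)
    return frozenset(out)


TYPE_GAP_RANGES: dict[str, tuple[frozenset, ...]] = {
    "type1": (
        _vals(9), _vals((13, 15), 19), _vals((19, 21)), _vals((20, 24)),
        _vals(7, 13, 14, 15),
    ),
    "type2": (
        _vals(3, 5, 7, (8, 10), 17), _vals(11, (12, 19), 21, 27),
        _vals((8, 13), 19), _vals(8, 10, 15, 18, 19, (21, 27), 36),
        _vals((3, 9), 11, 13, 15, 16, 17),
    ),
    "typeC": (_vals(9), _vals(14, 19), _vals(9), _vals(12), _vals(6)),
    "typeD": (
        _vals(9, 10, (12, 14)), _vals(14, (16, 18)), _vals((9, 12)),
        _vals(11, 17, 23, 24, 27), _vals(4, 7, 9, 10, 11, 20),
    ),
    "typeG": (
        _vals(6, 9, 10, 12), _vals(8, (13, 18), 20), _vals(12, 14, 19),
        _vals((21, 26), 29), _vals(5, 6, (8, 10), 13, 20),
    ),
}

#: diagnostic intron offset (nt after the last 8CM cysteine codon)
TYPE_INTRON_OFFSET = {"type1": 5, "typeC": 1, "typeD": 4}

#: fixed 25-residue hydrophobic signal-peptide stub (external-predictor stand-in)
SIGNAL_STUB = "MALLVLAVLALSVALGVAATSALLA"

#: residue pool for non-cysteine positions (all standard residues except C)
CYS_FREE_POOL = "ADEFGHIKLMNPQRSTVWY"

_SYN_CODONS: dict[str, list[str]] = {}
for _codon, _aa in CODON_TO_AA.items():
    _SYN_CODONS.setdefault(_aa, []).append(_codon)
for _aa in _SYN_CODONS:
    _SYN_CODONS[_aa].sort()

_NUCS = "ACGT"


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TandemArraySpec:
    chrom: int
    size: int
    syn_changes: int = 4
    nonsyn_changes: int = 2

    def __post_init__(self):
        if self.size < 2:
            raise ValueError("tandem array size must be >= 2")
        if self.syn_changes < 0 or self.nonsyn_changes < 0:
            raise ValueError("change counts must be non-negative")


#: paper-scale tissue panel: five tissues at three stages plus pistil/anther
DEFAULT_SAMPLES: dict[str, tuple[str, str]] = {
    "leaf_Z10": ("leaf", "Z10"), "leaf_Z23": ("leaf", "Z23"), "leaf_Z71": ("leaf", "Z71"),
    "root_Z10": ("root", "Z10"), "root_Z13": ("root", "Z13"), "root_Z39": ("root", "Z39"),
    "stem_Z30": ("stem", "Z30"), "stem_Z32": ("stem", "Z32"), "stem_Z65": ("stem", "Z65"),
    "spike_Z32": ("spike", "Z32"), "spike_Z39": ("spike", "Z39"), "spike_Z65": ("spike", "Z65"),
    "grain_Z71": ("grain", "Z71"), "grain_Z75": ("grain", "Z75"), "grain_Z85": ("grain", "Z85"),
    "pistil_1": ("pistil", "anthesis"), "pistil_2": ("pistil", "anthesis"),
    "anther_mei": ("anther", "meiosis"), "anther_uni": ("anther", "uninucleate"),
}


@dataclass(frozen=True)
class ExpressionSpec:
    """Log-normal FPKM model with planted anther-enriched and silent genes."""

    samples: tuple = tuple(DEFAULT_SAMPLES.items())
    target_tissue: str = "anther"
    frac_enriched: float = 17 / 461
    frac_not_expressed: float = 30 / 461
    enriched_target_mean: float = 60.0
    enriched_other_mean: float = 1.5
    background_mean: float = 5.0
    sigma: float = 0.5

    def __post_init__(self):
        tissues = {t for _, (t, _) in self.samples}
        if self.target_tissue not in tissues:
            raise ValueError(f"no {self.target_tissue!r} samples in expression spec")
        if len(tissues) < 2:
            raise ValueError("need at least two tissues")


@dataclass(frozen=True)
class PromoterSpec:
    """Planted-motif promoter sets over i.i.d. background."""

    motif: str = "AGAAA"
    n_pos: int = 17
    n_neg: int = 444
    length: int = 1000
    pos_freq: float = 0.9
    neg_freq: float = 0.1
    gc: float = 0.5

    def __post_init__(self):
        if len(self.motif) < 4:
            raise ValueError("motif length must be >= 4")
        if set(self.motif.upper()) - set(_NUCS):
            raise ValueError("planted motif must be plain ACGT")
        for f in (self.pos_freq, self.neg_freq):
            if not 0 <= f <= 1:
                raise ValueError("frequencies must lie in [0,1]")


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n_chromosomes: int = 3
    chrom_length_bp: int = 40_000
    n_ltp_genes: int = 50
    type_mix: tuple = (
        ("type1", 39 / 461), ("type2", 274 / 461), ("typeC", 5 / 461),
        ("typeD", 57 / 461), ("typeG", 86 / 461),
    )
    tandem_array_spec: tuple = (
        TandemArraySpec(0, 3), TandemArraySpec(1, 3), TandemArraySpec(2, 4),
    )
    expression: ExpressionSpec = ExpressionSpec()
    promoters: PromoterSpec = PromoterSpec()
    gc: float = 0.45
    allow_background_cysteines: bool = False

    def __post_init__(self):
        total = sum(p for _, p in self.type_mix)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"type mix proportions sum to {total}, not 1")
        n_array = sum(a.size for a in self.tandem_array_spec)
        if n_array > self.n_ltp_genes:
            raise ValueError("tandem arrays exceed n_ltp_genes")
        for a in self.tandem_array_spec:
            if a.chrom >= self.n_chromosomes:
                raise ValueError("array chromosome index out of range")


# ---------------------------------------------------------------------------
# truth bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class TruthGene:
    gene_id: str
    ltp_type: str
    gaps: tuple[int, int, int, int, int]
    cys_positions_mature: tuple[int, ...]
    signal_cleavage: int
    gpi_omega: int
    cluster_id: str = ""


@dataclass
class SyntheticTruth:
    genes: dict[str, TruthGene] = field(default_factory=dict)
    clusters: list[list[str]] = field(default_factory=list)
    #: (seed_gene, member_gene, syn, nonsyn) for every array member
    pairs: list[tuple[str, str, int, int]] = field(default_factory=list)

    def genes_tsv(self) -> str:
        lines = ["gene_id\ttype\tgaps\tcys_positions_mature\tsignal_cleavage\tgpi_omega\tcluster_id"]
        for g in self.genes.values():
            lines.append(
                f"{g.gene_id}\t{g.ltp_type}\t{','.join(map(str, g.gaps))}\t"
                f"{','.join(map(str, g.cys_positions_mature))}\t"
                f"{g.signal_cleavage}\t{g.gpi_omega}\t{g.cluster_id}"
            )
        return "\n".join(lines) + "\n"

    def clusters_tsv(self) -> str:
        lines = ["cluster_id\tmembers"]
        for i, members in enumerate(self.clusters, 1):
            lines.append(f"TD{i}\t{','.join(members)}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# low-level sequence helpers
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, length: int, gc: float, no_cys: bool) -> str:
    """Random DNA at the stated GC; with ``no_cys`` the cysteine codons
    TGT/TGC never occur as substrings (in any frame)."""
    if length == 0:
        return ""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)
    if no_cys and length >= 3:
        # rewrite the G of every TG[TC] to A; A can never complete TGT/TGC
        t, g, c = _NUCS.index("T"), _NUCS.index("G"), _NUCS.index("C")
        hit = (codes[:-2] == t) & (codes[1:-1] == g) & (
            (codes[2:] == t) | (codes[2:] == c)
        )
        codes[1:-1][hit] = _NUCS.index("A")
    return "".join(_NUCS[i] for i in codes)


def _codon_for(rng: np.random.Generator, aa: str) -> str:
    options = _SYN_CODONS[aa]
    return options[rng.integers(len(options))]


def _encode_protein(rng: np.random.Generator, protein: str) -> str:
    return "".join(_codon_for(rng, aa) for aa in protein)


def _sample_gaps(rng: np.random.Generator, ltp_type: str):
    return tuple(
        sorted(TYPE_GAP_RANGES[ltp_type][g])[rng.integers(len(TYPE_GAP_RANGES[ltp_type][g]))]
        for g in range(5)
    )


def _sample_types(rng: np.random.Generator, config: GeneratorConfig, n: int) -> list[str]:
    labels = [t for t, _ in config.type_mix]
    probs = np.array([p for _, p in config.type_mix])
    return [labels[i] for i in rng.choice(len(labels), size=n, p=probs / probs.sum())]


# ---------------------------------------------------------------------------
# single-gene construction
# ---------------------------------------------------------------------------

@dataclass
class _GeneUnit:
    ltp_type: str
    gaps: tuple
    protein: str
    cds: str  # includes the stop codon
    intron_prefixes: list[int]  # CDS bases 5' of each intron
    introns: list[str]
    signal_cleavage: int
    gpi_omega: int
    cys_positions_full: tuple


def _build_unit(rng: np.random.Generator, ltp_type: str, gaps=None) -> _GeneUnit:
    if ltp_type not in TYPE_GAP_RANGES:
        raise ValueError(f"unknown type {ltp_type!r}")
    if gaps is None:
        gaps = _sample_gaps(rng, ltp_type)
    gaps = tuple(gaps)
    for g, v in enumerate(gaps):
        if v not in TYPE_GAP_RANGES[ltp_type][g]:
            raise ValueError(
                f"{ltp_type}: gap g{g + 1}={v} outside the allowed spacing set"
            )
    pool = CYS_FREE_POOL

    def filler(n):
        return "".join(pool[i] for i in rng.integers(len(pool), size=n))

    nterm = filler(int(rng.integers(2, 8)))
    motif = (
        "C" + filler(gaps[0]) + "C" + filler(gaps[1]) + "CC" + filler(gaps[2])
        + "C" + filler(1) + "C" + filler(gaps[3]) + "C" + filler(gaps[4]) + "C"
    )
    if ltp_type == "typeG":
        tail, propep = filler(12), filler(10)
        protein = SIGNAL_STUB + nterm + motif + tail + propep
        omega = len(SIGNAL_STUB) + len(nterm) + len(motif) + len(tail)
    else:
        protein = SIGNAL_STUB + nterm + motif + filler(int(rng.integers(6, 13)))
        omega = 0

    cys_full = tuple(i for i, r in enumerate(protein) if r == "C")
    assert len(cys_full) == 8
    stop = ("TAA", "TGA", "TAG")[rng.integers(3)]
    cds = _encode_protein(rng, protein) + stop

    e = 3 * cys_full[7] + 2  # last base of the C8 codon, 0-based CDS index
    if ltp_type in TYPE_INTRON_OFFSET:
        prefixes = [e + TYPE_INTRON_OFFSET[ltp_type]]
    elif ltp_type == "typeG":
        n_introns = int(rng.integers(0, 5))
        sites = sorted(
            int(v) for v in rng.choice(
                np.arange(30, len(cds) - 3), size=n_introns, replace=False
            )
        ) if n_introns else []
        prefixes = sites
    else:  # type2: intronless
        prefixes = []
    introns = [
        "GT" + _random_dna(rng, int(rng.integers(60, 121)), 0.4, True) + "AG"
        for _ in prefixes
    ]
    return _GeneUnit(
        ltp_type, gaps, protein, cds, prefixes, introns,
        len(SIGNAL_STUB), omega, cys_full,
    )


def _unit_dna(unit: _GeneUnit) -> tuple[str, list[tuple[int, int]]]:
    """Gene DNA and exon spans relative to the gene start (plus strand)."""
    parts, exons = [], []
    g = last = 0
    for p, intron in zip(unit.intron_prefixes, unit.introns):
        parts.append(unit.cds[last:p])
        exons.append((g, g + p - last))
        g += p - last + len(intron)
        parts.append(intron)
        last = p
    parts.append(unit.cds[last:])
    exons.append((g, g + len(unit.cds) - last))
    return "".join(parts), exons


def generate_ltp_gene(ltp_type: str, gaps, seed: int):
    """Build one synthetic nsLTP gene of the requested type and spacing.

    Returns (GeneModel, gene DNA, MaturationAnnotation, TruthGene) with the
    model's coordinates relative to the gene's own sequence (plus strand).
    Identical inputs give byte-identical outputs.
    """
    rng = np.random.default_rng(seed)
    unit = _build_unit(rng, ltp_type, gaps)
    dna, exons = _unit_dna(unit)
    intervals = [GenomicInterval("gene", s, e, "+") for s, e in exons]
    model = GeneModel(
        "gene", GenomicInterval("gene", 0, len(dna), "+"), intervals, intervals
    )
    ann = MaturationAnnotation("gene", unit.signal_cleavage, unit.gpi_omega)
    truth = TruthGene(
        "gene", ltp_type, unit.gaps,
        tuple(c - unit.signal_cleavage for c in unit.cys_positions_full),
        unit.signal_cleavage, unit.gpi_omega,
    )
    return model, dna, ann, truth


# ---------------------------------------------------------------------------
# controlled CDS mutation
# ---------------------------------------------------------------------------

def mutate_cds_controlled(
    cds: str,
    syn_changes: int,
    nonsyn_changes: int,
    seed,
    protected_codons=frozenset(),
    forbid_new_cys: bool = True,
) -> str:
    """Apply exact counts of synonymous and non-synonymous single-nucleotide
    changes at distinct codons.

    Changes never create a stop codon, never touch protected codons (the
    8CM cysteines in the genome generator) and, by default, never create a
    new cysteine codon — keeping planted motifs the only 8CM instances.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if len(cds) % 3:
        raise ValueError("CDS length must be divisible by 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]

    def alternatives(codon, synonymous):
        aa = CODON_TO_AA[codon]
        out = []
        for pos in range(3):
            for n in _NUCS:
                if n == codon[pos]:
                    continue
                alt = codon[:pos] + n + codon[pos + 1 :]
                alt_aa = CODON_TO_AA[alt]
                if alt_aa == "*":
                    continue
                if forbid_new_cys and alt_aa == "C" and aa != "C":
                    continue
                if (alt_aa == aa) == synonymous:
                    out.append(alt)
        return sorted(out)

    eligible = {
        True: [
            i for i, c in enumerate(codons)
            if i not in protected_codons and CODON_TO_AA[c] != "*" and alternatives(c, True)
        ],
        False: [
            i for i, c in enumerate(codons)
            if i not in protected_codons and CODON_TO_AA[c] != "*" and alternatives(c, False)
        ],
    }
    chosen: dict[int, bool] = {}
    for synonymous, count in ((True, syn_changes), (False, nonsyn_changes)):
        avail = [i for i in eligible[synonymous] if i not in chosen]
        if len(avail) < count:
            raise ValueError(
                f"insufficient eligible codons: need {count} "
                f"{'synonymous' if synonymous else 'non-synonymous'} sites, "
                f"have {len(avail)}"
            )
        for idx in rng.choice(len(avail), size=count, replace=False):
            chosen[avail[int(idx)]] = synonymous
    for i, synonymous in chosen.items():
        alts = alternatives(codons[i], synonymous)
        codons[i] = alts[rng.integers(len(alts))]
    return "".join(codons)


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------

@dataclass
class SyntheticGenome:
    chromosomes: dict[str, str]
    models: list[GeneModel]
    annotations: dict[str, MaturationAnnotation]
    proteins: dict[str, str]
    cds: dict[str, str]
    truth: SyntheticTruth

    def fasta_records(self) -> list[SequenceRecord]:
        return [SequenceRecord.dna(c, s) for c, s in sorted(self.chromosomes.items())]


def _place_unit(chrom_seq: list[str], offset: int, unit: _GeneUnit, strand: str,
                chrom: str, gene_id: str):
    dna, exons_rel = _unit_dna(unit)
    L = len(dna)
    if strand == "-":
        placed = reverse_complement(dna)
        intervals = [
            GenomicInterval(chrom, offset + L - e, offset + L - s, "-")
            for s, e in exons_rel
        ]
    else:
        placed = dna
        intervals = [GenomicInterval(chrom, offset + s, offset + e, "+") for s, e in exons_rel]
    chrom_seq.append(placed)
    model = GeneModel(
        gene_id,
        GenomicInterval(chrom, offset, offset + L, strand),
        sorted(intervals, key=lambda iv: iv.start),
        sorted(intervals, key=lambda iv: iv.start),
    )
    return model, offset + L


def generate_genome(config: GeneratorConfig) -> SyntheticGenome:
    """Generate the full synthetic genome with recorded ground truth."""
    rng = np.random.default_rng(config.seed)
    truth = SyntheticTruth()

    n_array = sum(a.size for a in config.tandem_array_spec)
    n_single = config.n_ltp_genes - n_array
    single_types = _sample_types(rng, config, n_single)
    array_types = _sample_types(rng, config, len(config.tandem_array_spec))

    # build all gene units up front (deterministic order)
    counter = 0

    def next_id():
        nonlocal counter
        counter += 1
        return f"LTP{counter:04d}"

    # chromosome -> list of placement items; an item is a list of
    # (gene_id, unit, strand) tuples (singletons or whole arrays)
    per_chrom: dict[int, list] = {i: [] for i in range(config.n_chromosomes)}

    for ai, (spec, atype) in enumerate(zip(config.tandem_array_spec, array_types), 1):
        seed_unit = _build_unit(rng, atype)
        protected = frozenset(
            {0, len(seed_unit.cds) // 3 - 1}
            | {c for c in (p for p in seed_unit.cys_positions_full)}
        )
        strand = "+-"[rng.integers(2)]
        block, members = [], []
        seed_gid = None
        for m in range(spec.size):
            gid = next_id()
            if m == 0:
                unit = seed_unit
                seed_gid = gid
            else:
                cds = mutate_cds_controlled(
                    seed_unit.cds, spec.syn_changes, spec.nonsyn_changes, rng,
                    protected_codons=protected,
                )
                unit = _GeneUnit(
                    seed_unit.ltp_type, seed_unit.gaps,
                    "".join(CODON_TO_AA[cds[i : i + 3]] for i in range(0, len(cds) - 3, 3)),
                    cds, seed_unit.intron_prefixes,
                    [
                        "GT" + _random_dna(rng, int(rng.integers(60, 121)), 0.4, True) + "AG"
                        for _ in seed_unit.intron_prefixes
                    ],
                    seed_unit.signal_cleavage, seed_unit.gpi_omega,
                    seed_unit.cys_positions_full,
                )
                truth.pairs.append((seed_gid, gid, spec.syn_changes, spec.nonsyn_changes))
            block.append((gid, unit, strand))
            members.append(gid)
            truth.genes[gid] = TruthGene(
                gid, atype, unit.gaps,
                tuple(c - unit.signal_cleavage for c in unit.cys_positions_full),
                unit.signal_cleavage, unit.gpi_omega, f"TD{ai}",
            )
        truth.clusters.append(members)
        per_chrom[spec.chrom].append(block)

    for i, stype in enumerate(single_types):
        gid = next_id()
        unit = _build_unit(rng, stype)
        strand = "+-"[rng.integers(2)]
        truth.genes[gid] = TruthGene(
            gid, stype, unit.gaps,
            tuple(c - unit.signal_cleavage for c in unit.cys_positions_full),
            unit.signal_cleavage, unit.gpi_omega, "",
        )
        per_chrom[i % config.n_chromosomes].append([(gid, unit, strand)])

    chromosomes: dict[str, str] = {}
    models: list[GeneModel] = []
    annotations: dict[str, MaturationAnnotation] = {}
    proteins: dict[str, str] = {}
    cds_map: dict[str, str] = {}

    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        items = per_chrom[ci]
        order = rng.permutation(len(items))
        seq_parts: list[str] = []
        offset = 0
        for oi in order:
            for gid, unit, strand in items[int(oi)]:
                gap = int(rng.integers(300, 801))
                seq_parts.append(
                    _random_dna(rng, gap, config.gc, not config.allow_background_cysteines)
                )
                offset += gap
                model, offset = _place_unit(seq_parts, offset, unit, strand, chrom, gid)
                models.append(model)
                annotations[gid] = MaturationAnnotation(
                    gid, unit.signal_cleavage, unit.gpi_omega
                )
                proteins[gid] = unit.protein
                cds_map[gid] = unit.cds
        if offset > config.chrom_length_bp:
            raise ValueError(
                f"{chrom}: genes span {offset} bp, exceeding chrom_length_bp="
                f"{config.chrom_length_bp}"
            )
        seq_parts.append(
            _random_dna(rng, config.chrom_length_bp - offset, config.gc,
                        not config.allow_background_cysteines)
        )
        chromosomes[chrom] = "".join(seq_parts)

    models.sort(key=lambda m: (m.location.chrom, m.location.start, m.gene_id))
    return SyntheticGenome(chromosomes, models, annotations, proteins, cds_map, truth)


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------

def generate_expression_matrix(spec: ExpressionSpec, gene_ids: list[str], seed: int):
    """FPKM matrix with planted anther-enriched and all-zero genes.

    Returns (ExpressionMatrix, truth DataFrame with anther_enriched and
    not_expressed flags).
    """
    from .expression import ExpressionMatrix

    rng = np.random.default_rng(seed)
    gene_ids = list(gene_ids)
    n = len(gene_ids)
    n_enr = int(round(spec.frac_enriched * n))
    n_zero = int(round(spec.frac_not_expressed * n))
    picks = rng.choice(n, size=n_enr + n_zero, replace=False)
    enriched = {gene_ids[int(i)] for i in picks[:n_enr]}
    silent = {gene_ids[int(i)] for i in picks[n_enr:]}

    samples = dict(spec.samples)
    cols = list(samples)
    data = np.zeros((n, len(cols)))
    for gi, gid in enumerate(gene_ids):
        for si, s in enumerate(cols):
            tissue = samples[s][0]
            if gid in silent:
                continue
            if gid in enriched:
                mean = (
                    spec.enriched_target_mean
                    if tissue == spec.target_tissue
                    else spec.enriched_other_mean
                )
            else:
                mean = spec.background_mean
            data[gi, si] = rng.lognormal(math.log(mean), spec.sigma)
    em = ExpressionMatrix(
        pd.DataFrame(data, index=gene_ids, columns=cols),
        {s: t for s, (t, _) in samples.items()},
        {s: st for s, (_, st) in samples.items()},
    )
    flags = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "anther_enriched": [g in enriched for g in gene_ids],
            "not_expressed": [g in silent for g in gene_ids],
        }
    ).set_index("gene_id")
    return em, flags


# ---------------------------------------------------------------------------
# promoter sets
# ---------------------------------------------------------------------------

def generate_promoter_sets(spec: PromoterSpec, seed: int):
    """Positive/negative promoter sets with the planted motif inserted at
    the stated per-set frequencies; returns (pos, neg, placements) where
    placements are (set_label, seq_index, position, strand) tuples."""
    rng = np.random.default_rng(seed)
    placements = []

    def make_set(label, n, freq):
        records = []
        p = np.array([(1 - spec.gc) / 2, spec.gc / 2, spec.gc / 2, (1 - spec.gc) / 2])
        for i in range(n):
            bases = rng.choice(4, size=spec.length, p=p)
            seq = "".join(_NUCS[b] for b in bases)
            if rng.random() < freq:
                pos = int(rng.integers(0, spec.length - len(spec.motif) + 1))
                strand = "+-"[rng.integers(2)]
                ins = spec.motif if strand == "+" else reverse_complement(spec.motif)
                seq = seq[:pos] + ins + seq[pos + len(ins) :]
                placements.append((label, i, pos, strand))
            records.append(SequenceRecord.dna(f"{label}_{i + 1}", seq))
        return records

    pos = make_set("pos", spec.n_pos, spec.pos_freq)
    neg = make_set("neg", spec.n_neg, spec.neg_freq)
    return pos, neg, placements
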