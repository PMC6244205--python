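"""Homology pairs (80/80 rule), tandem clusters, NG86 Ka/Ks and dating.

Ka/Ks uses the Nei-Gojobori (1986) pathway-counting method: per-codon
synonymous site fractions from the standard genetic code (sites averaged
over the two sequences), multiple-hit codons resolved by averaging the
synonymous/non-synonymous split over all orderings of the changed
positions, and Jukes-Cantor correction d = -(3/4) ln(1 - 4p/3). Mutations
passing through a stop codon are counted as non-synonymous. Divergence
times come from T = Ks / (2 r), reported in MYA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations

from .align import align_global_nuc
from .core_io import CODON_TO_AA

NUCS = "ACGT"

#: default synonymous-rate constant (substitutions/site/year) for dating
DEFAULT_RATE = 6.5e-9


@dataclass(frozen=True)
class HomologyPair:
    """Unordered gene pair with alignment coverage and identity."""

    gene_a: str
    gene_b: str
    coverage: float
    identity: float

    def __post_init__(self):
        for v in (self.coverage, self.identity):
            if not 0 <= v <= 1 + 1e-12:
                raise ValueError("coverage/identity outside [0,1]")

    @property
    def key(self) -> frozenset:
        return frozenset((self.gene_a, self.gene_b))


@dataclass
class TandemCluster:
    chrom: str
    members: list[str]  # ordered by chromosome position

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError("a tandem cluster needs >=2 members")


@dataclass
class KaKsResult:
    gene_a: str
    gene_b: str
    ka: float | None
    ks: float | None
    ratio: float | None
    t_mya: float | None = None
    syn_sites: float = 0.0
    nonsyn_sites: float = 0.0
    syn_diffs: float = 0.0
    nonsyn_diffs: float = 0.0
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# alignment and the 80/80 homology rule
# ---------------------------------------------------------------------------

def align_cds_pair(cds_a: str, cds_b: str):
    """Global nucleotide alignment with a codon-aware projection.

    Returns (coverage, identity, codon_pairs): coverage is the aligned
    (both-non-gap) fraction of the shorter CDS, identity the match fraction
    over aligned columns, and codon_pairs the in-frame gap-free codon pairs
    available for Ka/Ks counting.
    """
    if len(cds_a) % 3 or len(cds_b) % 3:
        raise ValueError("CDS lengths must be divisible by 3")
    ga, gb = align_global_nuc(cds_a, cds_b)
    pairs = []  # (a_pos, b_pos) of aligned non-gap columns
    ia = ib = 0
    matches = aligned = 0
    for x, y in zip(ga, gb):
        if x != "-" and y != "-":
            pairs.append((ia, ib))
            aligned += 1
            if x == y:
                matches += 1
        if x != "-":
            ia += 1
        if y != "-":
            ib += 1
    coverage = aligned / min(len(cds_a), len(cds_b))
    identity = matches / aligned if aligned else 0.0

    pos_of = dict(pairs)
    codon_pairs = []
    for k in range(len(cds_a) // 3):
        a0 = 3 * k
        bs = [pos_of.get(a0 + j) for j in range(3)]
        if None in bs:
            continue
        b0 = bs[0]
        if bs != [b0, b0 + 1, b0 + 2] or b0 % 3:
            continue
        codon_pairs.append((cds_a[a0 : a0 + 3], cds_b[b0 : b0 + 3]))
    return coverage, identity, codon_pairs


def is_homologous_pair(
    pair: HomologyPair, cov_min: float = 0.80, id_min: float = 0.80
) -> bool:
    """The 80/80 rule: coverage >= 80% and identity strictly above 80%."""
    return pair.coverage >= cov_min and pair.identity > id_min


def all_pairs_homology(cds_by_gene: dict[str, str]) -> list[HomologyPair]:
    """HomologyPair for every unordered gene pair (deterministic order)."""
    ids = sorted(cds_by_gene)
    out = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            cov, ident, _ = align_cds_pair(cds_by_gene[a], cds_by_gene[b])
            out.append(HomologyPair(a, b, cov, ident))
    return out


# ---------------------------------------------------------------------------
# tandem clusters
# ---------------------------------------------------------------------------

def find_tandem_clusters(
    gene_order: dict[str, list[str]],
    homologous_pairs: set[frozenset],
    max_intervening: int = 0,
) -> list[TandemCluster]:
    """Single-linkage chains of adjacent homologous family genes.

    ``gene_order`` maps each chromosome to its family genes sorted by
    position. Two genes chain together when they are homologous and
    separated by at most ``max_intervening`` family genes in that order;
    clusters are the maximal chains with >=2 members and form a partition.
    """
    clusters = []
    for chrom in sorted(gene_order):
        order = gene_order[chrom]
        rank = {g: i for i, g in enumerate(order)}
        parent = {g: g for g in order}

        def find(g):
            while parent[g] != g:
                parent[g] = parent[parent[g]]
                g = parent[g]
            return g

        for i, a in enumerate(order):
            for b in order[i + 1 : i + 2 + max_intervening]:
                if frozenset((a, b)) in homologous_pairs:
                    parent[find(a)] = find(b)
        groups: dict[str, list[str]] = {}
        for g in order:
            groups.setdefault(find(g), []).append(g)
        for members in groups.values():
            if len(members) >= 2:
                members.sort(key=rank.get)
                clusters.append(TandemCluster(chrom, members))
    clusters.sort(key=lambda c: (c.chrom, c.members[0]))
    return clusters


# ---------------------------------------------------------------------------
# NG86
# ---------------------------------------------------------------------------

def _syn_site_fraction(codon: str) -> float:
    """Synonymous site count of one codon (0..3); stop changes count as
    non-synonymous."""
    aa = CODON_TO_AA[codon]
    syn = 0
    for pos in range(3):
        for n in NUCS:
            if n == codon[pos]:
                continue
            alt = codon[:pos] + n + codon[pos + 1 :]
            alt_aa = CODON_TO_AA[alt]
            if alt_aa == aa and alt_aa != "*":
                syn += 1
    return syn / 3.0


def _pathway_counts(ca: str, cb: str) -> tuple[float, float]:
    """Average (syn, nonsyn) difference counts over all minimal mutational
    pathways between two codons; steps through stops count as non-synonymous."""
    diff = [i for i in range(3) if ca[i] != cb[i]]
    if not diff:
        return 0.0, 0.0
    syn_total = nonsyn_total = 0.0
    npaths = 0
    for order in permutations(diff):
        cur = ca
        s = n = 0
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if (
                CODON_TO_AA[cur] == CODON_TO_AA[nxt]
                and CODON_TO_AA[cur] != "*"
                and CODON_TO_AA[nxt] != "*"
            ):
                s += 1
            else:
                n += 1
            cur = nxt
        syn_total += s
        nonsyn_total += n
        npaths += 1
    return syn_total / npaths, nonsyn_total / npaths


def jukes_cantor(p: float) -> float:
    """Multiple-hit correction d = -(3/4) ln(1 - 4p/3); undefined for p >= 3/4."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        raise ValueError("saturated: p >= 3/4")
    return -0.75 * math.log(1 - 4 * p / 3)


def ng86_kaks(codon_pairs, gene_a: str = "a", gene_b: str = "b") -> KaKsResult:
    """Nei-Gojobori Ka/Ks over gap-free aligned codon pairs."""
    if not codon_pairs:
        raise ValueError("no gap-free codon pairs to analyse")
    s_a = s_b = sd = nd = 0.0
    for ca, cb in codon_pairs:
        s_a += _syn_site_fraction(ca)
        s_b += _syn_site_fraction(cb)
        ds, dn = _pathway_counts(ca, cb)
        sd += ds
        nd += dn
    total = 3.0 * len(codon_pairs)
    S = (s_a + s_b) / 2
    N = total - S
    res = KaKsResult(
        gene_a, gene_b, None, None, None,
        syn_sites=S, nonsyn_sites=N, syn_diffs=sd, nonsyn_diffs=nd,
    )
    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0
    try:
        res.ks = jukes_cantor(ps)
    except ValueError:
        res.flags.append("ks_saturated")
    try:
        res.ka = jukes_cantor(pn)
    except ValueError:
        res.flags.append("ka_saturated")
    if res.ka is not None and res.ks is not None:
        if res.ks > 0:
            res.ratio = res.ka / res.ks
        else:
            res.flags.append("ks_zero")
    if res.ks is not None:
        res.t_mya = divergence_time_mya(res.ks)
    return res


def divergence_time_mya(ks: float, r: float = DEFAULT_RATE) -> float:
    """Duplication age T = Ks / (2 r), in million years."""
    if ks < 0:
        raise ValueError("Ks must be non-negative")
    if r <= 0:
        raise ValueError("rate must be positive")
    return ks / (2 * r) * 1e-6
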