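"""Promoter motif enrichment: known-motif rank-sum tests and de novo
k-mer discovery.

Two complementary tests mirror the standard motif-enrichment toolbox:

* known motifs are scored per promoter by occurrence count (both strands,
  overlapping) and compared between positive and negative promoter sets by
  a one-sided Wilcoxon rank-sum test (normal approximation with tie
  correction) — the AME-style test;
* de novo discovery enumerates k-mers present in the positive set
  (canonicalized over reverse complement), scores sequence-level presence
  by a one-sided Fisher's exact test, Bonferroni-corrects by the number of
  candidates tested into an E-value, accepts the best motif if E is below
  threshold, erases its sites and repeats — the DREME-style loop, with at
  most one IUPAC-wildcard generalization per motif.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.stats import hypergeom, mannwhitneyu

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: two-base IUPAC code for an unordered base pair
_PAIR_CODE = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}


def revcomp_iupac(motif: str) -> str:
    return motif.translate(_COMP)[::-1]


@dataclass(frozen=True)
class KnownMotif:
    name: str
    consensus: str

    def __post_init__(self):
        if len(self.consensus) < 4:
            raise ValueError(f"{self.name}: motif shorter than 4")
        bad = set(self.consensus.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"{self.name}: invalid IUPAC letters {sorted(bad)}")
        object.__setattr__(self, "consensus", self.consensus.upper())


@dataclass
class EnrichmentResult:
    motif: KnownMotif
    test: str
    p_value: float
    significant: bool
    degenerate: bool = False


@dataclass
class DiscoveredMotif:
    consensus: str
    p_value: float
    e_value: float
    pos_hits: int
    neg_hits: int
    n_candidates: int
    sites: list[tuple[int, int, str]] = field(default_factory=list)  # (seq, pos, strand)
    pcm: np.ndarray | None = None  # len(consensus) x 4 counts, ACGT order


def load_pollen_boxes(path=None) -> list[KnownMotif]:
    """The editable known-box table (pollen/anther cis-element candidates)."""
    if path is None:
        text = resources.files("nsltp.data").joinpath("pollen_boxes.tsv").read_text()
    else:
        text = open(path).read()
    boxes = []
    for line in text.splitlines():
        if line.strip() and not line.startswith("#"):
            name, consensus = line.split("\t")[:2]
            boxes.append(KnownMotif(name, consensus))
    return boxes


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _pattern(motif: str) -> str:
    return "".join(f"[{IUPAC[c]}]" for c in motif)


def scan_motif(promoter: str, motif: KnownMotif | str) -> int:
    """Overlapping occurrence count on both strands; a palindromic motif is
    counted on one strand only so sites are never double-counted."""
    consensus = motif.consensus if isinstance(motif, KnownMotif) else motif.upper()
    seq = promoter.upper()
    count = len(re.findall(f"(?={_pattern(consensus)})", seq))
    rc = revcomp_iupac(consensus)
    if rc != consensus:
        count += len(re.findall(f"(?={_pattern(rc)})", seq))
    return count


def ranksum_known_motif(
    pos_seqs: list[str],
    neg_seqs: list[str],
    motif: KnownMotif,
    alpha: float = 0.05,
) -> EnrichmentResult:
    """One-sided Wilcoxon rank-sum on per-promoter occurrence counts."""
    if not pos_seqs or not neg_seqs:
        raise ValueError("both promoter sets must be non-empty")
    pos = [scan_motif(s, motif) for s in pos_seqs]
    neg = [scan_motif(s, motif) for s in neg_seqs]
    if not any(pos) and not any(neg):
        return EnrichmentResult(motif, "ranksum", 1.0, False, degenerate=True)
    if len(set(pos + neg)) == 1:
        # identical scores everywhere: no ordering information
        return EnrichmentResult(motif, "ranksum", 0.5, False)
    _, p = mannwhitneyu(
        pos, neg, alternative="greater", method="asymptotic", use_continuity=True
    )
    p = float(min(max(p, np.nextafter(0, 1)), 1.0))
    return EnrichmentResult(motif, "ranksum", p, p < alpha)


def pollen_box_screen(
    pos_seqs: list[str],
    neg_seqs: list[str],
    boxes: list[KnownMotif] | None = None,
    alpha: float = 0.05,
):
    """Rank-sum enrichment for each candidate box, one row per box.

    P-values are reported per box at the stated alpha with no
    multiple-testing correction (the note column records this).
    """
    import pandas as pd

    if boxes is None:
        boxes = load_pollen_boxes()
    rows = []
    for box in boxes:
        res = ranksum_known_motif(pos_seqs, neg_seqs, box, alpha)
        rows.append(
            {
                "name": box.name,
                "consensus": box.consensus,
                "p_value": res.p_value,
                "significant": res.significant,
                "degenerate": res.degenerate,
                "note": "per-box threshold, no multiple-testing correction",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# de novo discovery
# ---------------------------------------------------------------------------

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_BASE = "ACGT"


def _encode(seq: str) -> np.ndarray:
    arr = np.full(len(seq), 4, dtype=np.int64)
    for b, c in _BASE_CODE.items():
        arr[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = c
    return arr


def _canonical_kmers(arr: np.ndarray, k: int) -> np.ndarray:
    """Sorted distinct canonical (min of k-mer/revcomp codes) k-mers of one
    sequence; windows containing non-ACGT are skipped."""
    if len(arr) < k:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(arr, k)
    valid = (win < 4).all(axis=1)
    if not valid.any():
        return np.empty(0, dtype=np.int64)
    win = win[valid]
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    fwd = win @ powers
    rc = (3 - win) @ powers[::-1]
    return np.unique(np.minimum(fwd, rc))


def _code_to_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_CODE_BASE[code % 4])
        code //= 4
    return "".join(reversed(out))


def _kmer_to_code(kmer: str) -> int:
    code = 0
    for b in kmer:
        code = code * 4 + _BASE_CODE[b]
    return code


def _canonical_code(kmer: str) -> int:
    return min(_kmer_to_code(kmer), _kmer_to_code(revcomp_iupac(kmer)))


def _presence(seq_kmer_arrays: list[np.ndarray], codes: list[int]) -> int:
    codes = np.asarray(sorted(set(codes)), dtype=np.int64)
    n = 0
    for s in seq_kmer_arrays:  # each array is sorted unique
        if len(s):
            i = np.clip(np.searchsorted(s, codes), 0, len(s) - 1)
            if (s[i] == codes).any():
                n += 1
    return n


def _sequence_counts(seq_kmer_arrays: list[np.ndarray]):
    """(codes, counts): number of sequences containing each distinct k-mer."""
    nonempty = [a for a in seq_kmer_arrays if len(a)]
    if not nonempty:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(nonempty), return_counts=True)


def discover_motifs(
    pos_seqs: list[str],
    neg_seqs: list[str],
    k_range: range = range(4, 9),
    e_threshold: float = 0.05,
    max_motifs: int = 10,
    generalize: bool = True,
) -> list[DiscoveredMotif]:
    """Iterative DREME-style discovery of enriched k-mer motifs.

    Candidates are all canonical k-mers present in at least one positive
    promoter, for each k in ``k_range``; the Fisher p-value compares
    sequence-level presence between sets. Reported E-values are Bonferroni
    products p x (candidates tested) and are kept non-decreasing down the
    accepted list.
    """
    pos = [s.upper() for s in pos_seqs]
    neg = [s.upper() for s in neg_seqs]
    n_pos, n_neg = len(pos), len(neg)
    if not n_pos or not n_neg:
        raise ValueError("both promoter sets must be non-empty")
    neg_enc = [_encode(s) for s in neg]
    neg_sets_by_k = {k: [_canonical_kmers(e, k) for e in neg_enc] for k in k_range}
    neg_counts_by_k = {k: _sequence_counts(neg_sets_by_k[k]) for k in k_range}
    accepted: list[DiscoveredMotif] = []
    prev_e = 0.0

    for _ in range(max_motifs):
        best = None  # (p, k, code)
        n_candidates = 0
        pos_sets_by_k = {}
        pos_enc = [_encode(s) for s in pos]
        for k in k_range:
            pos_sets = [_canonical_kmers(e, k) for e in pos_enc]
            pos_sets_by_k[k] = pos_sets
            codes, a = _sequence_counts(pos_sets)
            if not len(codes):
                continue
            neg_codes, neg_counts = neg_counts_by_k[k]
            idx = np.searchsorted(neg_codes, codes)
            idx = np.clip(idx, 0, max(len(neg_codes) - 1, 0))
            b = np.where(
                (len(neg_codes) > 0) & (neg_codes[idx] == codes), neg_counts[idx], 0
            ) if len(neg_codes) else np.zeros(len(codes), dtype=np.int64)
            n_candidates += len(codes)
            pvals = hypergeom.sf(a - 1, n_pos + n_neg, a + b, n_pos)
            order = np.lexsort((codes, pvals))
            i = order[0]
            cand = (float(pvals[i]), k, int(codes[i]))
            if best is None or cand < best:
                best = cand
        if best is None:
            break
        p_best, k, code = best
        seed = _code_to_kmer(code, k)
        variant_codes = [code]
        consensus = seed
        n_tested = n_candidates

        if generalize:
            pos_sets = pos_sets_by_k[k]
            neg_sets = neg_sets_by_k[k]
            for i in range(k):
                for alt in "ACGT":
                    if alt == seed[i]:
                        continue
                    n_tested += 1
                    variant = seed[:i] + alt + seed[i + 1 :]
                    codes2 = [code, _canonical_code(variant)]
                    a2 = _presence(pos_sets, codes2)
                    b2 = _presence(neg_sets, codes2)
                    p2 = float(hypergeom.sf(a2 - 1, n_pos + n_neg, a2 + b2, n_pos))
                    if p2 < p_best:
                        p_best = p2
                        variant_codes = codes2
                        wc = _PAIR_CODE[frozenset((seed[i], alt))]
                        consensus = seed[:i] + wc + seed[i + 1 :]

        e_value = max(p_best * n_tested, prev_e)
        if e_value > e_threshold:
            break

        pos_hits = _presence(pos_sets_by_k[k], variant_codes)
        neg_hits = _presence(neg_sets_by_k[k], variant_codes)
        motif = DiscoveredMotif(
            consensus, p_best, e_value, pos_hits, neg_hits, n_tested
        )
        _collect_sites_and_erase(pos, motif)
        accepted.append(motif)
        prev_e = e_value
    return accepted


def _collect_sites_and_erase(pos: list[str], motif: DiscoveredMotif) -> None:
    """Record every site of a motif in the positive set (oriented to the
    motif strand), accumulate the position-count matrix, and erase the
    matched bases so later rounds cannot rediscover the same signal."""
    k = len(motif.consensus)
    fwd = re.compile(f"(?={_pattern(motif.consensus)})")
    rc_cons = revcomp_iupac(motif.consensus)
    rev = None if rc_cons == motif.consensus else re.compile(f"(?={_pattern(rc_cons)})")
    pcm = np.zeros((k, 4), dtype=int)
    for idx, seq in enumerate(pos):
        hits = [(m.start(), "+") for m in fwd.finditer(seq)]
        if rev is not None:
            hits += [(m.start(), "-") for m in rev.finditer(seq)]
        if not hits:
            continue
        chars = list(seq)
        for start, strand in sorted(hits):
            site = seq[start : start + k]
            if strand == "-":
                site = site.translate(_COMP)[::-1]
            for j, b in enumerate(site):
                if b in _BASE_CODE:
                    pcm[j, _BASE_CODE[b]] += 1
            motif.sites.append((idx, start, strand))
            chars[start : start + k] = "N" * k
        pos[idx] = "".join(chars)
    motif.pcm = pcm


def pcm_to_meme_text(motif: DiscoveredMotif) -> str:
    """Minimal MEME-format block for one discovered motif's site counts."""
    total = motif.pcm.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        freqs = np.where(total > 0, motif.pcm / np.maximum(total, 1), 0.25)
    lines = [
        f"MOTIF {motif.consensus}",
        f"letter-probability matrix: alength= 4 w= {len(motif.consensus)} "
        f"nsites= {int(motif.pcm.sum() / max(len(motif.consensus), 1))} E= {motif.e_value:.3g}",
    ]
    for row in freqs:
        lines.append(" ".join(f"{v:.6f}" for v in row))
    return "\n".join(lines) + "\n"
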