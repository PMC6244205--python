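"""Known-motif rank-sum enrichment and de novo k-mer discovery."""

import numpy as np
import pytest

from nsltp.promoter import (
    IUPAC,
    KnownMotif,
    discover_motifs,
    load_pollen_boxes,
    pollen_box_screen,
    ranksum_known_motif,
    revcomp_iupac,
    scan_motif,
)
from nsltp.synthetic import PromoterSpec, generate_promoter_sets

from .oracles import hypergeom_tail, naive_motif_count

AGAAA = KnownMotif("POLLEN1LELAT52", "AGAAA")


def _random_seqs(rng, n, length):
    return ["".join("ACGT"[i] for i in rng.integers(0, 4, length)) for _ in range(n)]


def motif_compatible(consensus, planted):
    """True when the planted k-mer (or its reverse complement) is contained
    in the IUPAC expansion of the discovered consensus."""
    if len(consensus) != len(planted):
        return False
    return any(
        all(b in IUPAC[c] for b, c in zip(cand, consensus))
        for cand in (planted, revcomp_iupac(planted))
    )


class TestScanMotif:
    def test_overlapping_occurrences(self):
        assert scan_motif("AGAAAGAAA", AGAAA) == 2

    def test_absent_motif(self):
        assert scan_motif("CCCCCC", AGAAA) == 0

    def test_reverse_strand_counted(self):
        assert scan_motif("TTTCT", AGAAA) == 1

    @pytest.mark.parametrize("motif", ["AGAAA", "ACGT", "GGWCC"])
    def test_matches_naive_oracle(self, motif):
        rng = np.random.default_rng(8)
        km = KnownMotif("m", motif)
        for seq in _random_seqs(rng, 30, 200):
            assert scan_motif(seq, km) == naive_motif_count(
                seq, motif, IUPAC, revcomp_iupac
            )


class TestRanksum:
    def test_identical_sets_not_significant(self):
        rng = np.random.default_rng(1)
        seqs = _random_seqs(rng, 20, 500)
        res = ranksum_known_motif(seqs, seqs, AGAAA)
        assert res.p_value == pytest.approx(0.5, abs=0.05)
        assert not res.significant

    def test_absent_motif_degenerate(self):
        res = ranksum_known_motif(["CCCC" * 50], ["GGGG" * 50], AGAAA)
        assert res.p_value == 1.0 and res.degenerate

    def test_power_at_paper_set_sizes(self):
        """AGAAA planted in 90% of 17 positives vs 10% of 444 negatives is
        detected at p<0.05 in at least 95% of 100 seeds.

        300-bp promoters keep chance occurrences of the 5-mer from drowning
        the single planted site; with 1-kb backgrounds a 5-mer occurs ~2x
        per sequence by chance and no per-sequence count test has this power.
        """
        spec = PromoterSpec(length=300)  # paper-sized sets, short background
        hits = 0
        for seed in range(100):
            pos, neg, _ = generate_promoter_sets(spec, 5000 + seed)
            res = ranksum_known_motif(
                [r.residues for r in pos], [r.residues for r in neg], AGAAA
            )
            hits += res.significant
        assert hits >= 95


class TestPollenBoxScreen:
    def test_default_table_has_pollen_box(self):
        boxes = load_pollen_boxes()
        assert any(b.name == "POLLEN1LELAT52" and b.consensus == "AGAAA" for b in boxes)

    def test_planted_box_dominates_screen(self):
        """With strong planting of one box among nine, the planted box is
        significant and carries the smallest p-value in at least 90% of
        seeds; unplanted boxes fire at roughly the per-box alpha rate (no
        multiple-testing correction is applied, so occasional chance hits
        in the small positive set are expected and correct)."""
        boxes = [AGAAA] + [
            KnownMotif(f"box{i}", m)
            for i, m in enumerate(
                ["TCCACCATA", "CGGTCAGT", "TTGACCGG", "ACGTCGCA", "GGCCATTG",
                 "CATGCCGC", "TGGTTAGG", "CCGTCGAA"]
            )
        ]
        top = 0
        spurious = 0
        for seed in range(10):
            pos, neg, _ = generate_promoter_sets(PromoterSpec(length=300), 300 + seed)
            table = pollen_box_screen(
                [r.residues for r in pos], [r.residues for r in neg], boxes
            ).set_index("name")
            if table.loc["POLLEN1LELAT52", "significant"] and (
                table["p_value"].idxmin() == "POLLEN1LELAT52"
            ):
                top += 1
            spurious += int(table["significant"].sum()) - int(
                table.loc["POLLEN1LELAT52", "significant"]
            )
        assert top >= 9
        assert spurious / 10 <= 2.0  # far below the 8 null boxes per run

    def test_short_promoters_degenerate(self):
        table = pollen_box_screen(["ACG"], ["ACG"], [AGAAA])
        assert table.loc[0, "degenerate"] and table.loc[0, "p_value"] == 1.0

    def test_empty_box_list(self):
        assert pollen_box_screen(["ACGT" * 10], ["ACGT" * 10], []).empty


class TestDiscoverMotifs:
    def test_fisher_p_equals_hypergeometric_tail(self):
        from scipy.stats import hypergeom

        for a, b, n_pos, n_neg in [(5, 1, 10, 20), (3, 3, 6, 6), (8, 0, 8, 30)]:
            p = float(hypergeom.sf(a - 1, n_pos + n_neg, a + b, n_pos))
            assert p == pytest.approx(hypergeom_tail(a, n_pos, b, n_neg))

    def test_identical_sets_yield_nothing(self):
        rng = np.random.default_rng(2)
        seqs = _random_seqs(rng, 15, 300)
        assert discover_motifs(seqs, seqs) == []

    def test_planted_eight_mer_recovered(self):
        spec = PromoterSpec(
            motif="TACGGTCA", n_pos=50, n_neg=200, pos_freq=0.8, neg_freq=0.05
        )
        pos, neg, _ = generate_promoter_sets(spec, 77)
        motifs = discover_motifs(
            [r.residues for r in pos], [r.residues for r in neg]
        )
        assert motifs and motif_compatible(motifs[0].consensus, "TACGGTCA")
        assert motifs[0].pos_hits > motifs[0].neg_hits

    def test_e_values_monotone_down_the_list(self):
        spec = PromoterSpec(
            motif="TACGGTCA", n_pos=40, n_neg=100, pos_freq=0.9, neg_freq=0.0,
            length=400,
        )
        pos, neg, _ = generate_promoter_sets(spec, 13)
        # plant a second, weaker motif into some positives
        pos = [r.residues for r in pos]
        pos = [
            ("GGATCCGG" + s[8:]) if i % 2 else s for i, s in enumerate(pos)
        ]
        motifs = discover_motifs(pos, [r.residues for r in neg])
        evals = [m.e_value for m in motifs]
        assert evals == sorted(evals)

    def test_null_false_discovery_rate(self):
        """On i.i.d. random sets the E<=0.05 acceptance fires in at most 10%
        of 500 seeds."""
        false_hits = 0
        for seed in range(500):
            rng = np.random.default_rng(20_000 + seed)
            pos = _random_seqs(rng, 10, 200)
            neg = _random_seqs(rng, 10, 200)
            if discover_motifs(pos, neg):
                false_hits += 1
        assert false_hits / 500 <= 0.10

    def test_invariant_to_reverse_complementing_inputs(self):
        spec = PromoterSpec(
            motif="TACGGTCA", n_pos=30, n_neg=60, pos_freq=0.9, neg_freq=0.0,
            length=300,
        )
        pos, neg, _ = generate_promoter_sets(spec, 21)
        pos = [r.residues for r in pos]
        neg = [r.residues for r in neg]
        a = discover_motifs(pos, neg)
        from nsltp.core_io import reverse_complement

        b = discover_motifs(
            [reverse_complement(s) for s in pos], [reverse_complement(s) for s in neg]
        )
        def canon(c):
            return min(c, revcomp_iupac(c))
        assert [canon(m.consensus) for m in a] == [canon(m.consensus) for m in b]

    def test_sites_and_pcm_consistent(self):
        spec = PromoterSpec(
            motif="TACGGTCA", n_pos=30, n_neg=60, pos_freq=1.0, neg_freq=0.0,
            length=300,
        )
        pos, neg, _ = generate_promoter_sets(spec, 31)
        motifs = discover_motifs(
            [r.residues for r in pos], [r.residues for r in neg], generalize=False
        )
        m = motifs[0]
        assert m.pcm.shape == (len(m.consensus), 4)
        assert m.pcm.sum() == len(m.sites) * len(m.consensus)
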