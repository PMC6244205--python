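"""Generator ground truth: planted motifs, introns, mutations, consistency."""

import numpy as np
import pytest

from nsltp.core_io import CODON_TO_AA, extract_spliced_cds, translate
from nsltp.synthetic import (
    GeneratorConfig,
    PromoterSpec,
    TYPE_GAP_RANGES,
    generate_genome,
    generate_ltp_gene,
    generate_promoter_sets,
    mutate_cds_controlled,
    _sample_types,
)


class TestGenerateLtpGene:
    def test_type_c_gaps_and_intron_offset(self):
        model, dna, ann, truth = generate_ltp_gene("typeC", (9, 14, 9, 12, 6), seed=0)
        cds = extract_spliced_cds(model, {"gene": dna}).residues
        protein = translate(cds)[:-1]
        cys = [i for i, r in enumerate(protein) if r == "C"]
        gaps = (cys[1] - cys[0] - 1, cys[2] - cys[1] - 1, cys[4] - cys[3] - 1,
                cys[6] - cys[5] - 1, cys[7] - cys[6] - 1)
        assert gaps == (9, 14, 9, 12, 6)
        # one intron, 1 nt after the last 8CM cysteine codon
        prefixes = model.cds_intron_prefixes()
        assert len(prefixes) == 1
        assert prefixes[0] - (3 * cys[7] + 2) == 1

    @pytest.mark.parametrize("ltp_type,offset", [("type1", 5), ("typeD", 4)])
    def test_diagnostic_intron_offsets(self, ltp_type, offset):
        gaps = tuple(sorted(TYPE_GAP_RANGES[ltp_type][g])[0] for g in range(5))
        model, dna, _, _ = generate_ltp_gene(ltp_type, gaps, seed=1)
        cds = extract_spliced_cds(model, {"gene": dna}).residues
        cys = [i for i, r in enumerate(translate(cds)) if r == "C"]
        assert model.cds_intron_prefixes() == [3 * cys[7] + 2 + offset]

    def test_type2_has_no_introns(self):
        model, _, ann, _ = generate_ltp_gene("type2", (3, 11, 8, 8, 3), seed=2)
        assert model.cds_intron_prefixes() == []
        assert ann.gpi_omega == 0

    def test_type_g_has_omega_site(self):
        model, dna, ann, truth = generate_ltp_gene("typeG", (6, 8, 12, 21, 5), seed=3)
        assert ann.gpi_omega > ann.signal_cleavage
        assert len(model.cds_intron_prefixes()) <= 4

    def test_gaps_outside_type_range_rejected(self):
        with pytest.raises(ValueError, match="g4"):
            generate_ltp_gene("typeC", (9, 14, 9, 13, 6), seed=0)

    def test_same_seed_byte_identical(self):
        a = generate_ltp_gene("type1", (9, 13, 19, 20, 7), seed=9)
        b = generate_ltp_gene("type1", (9, 13, 19, 20, 7), seed=9)
        assert a[1] == b[1] and a[0].cds_exons == b[0].cds_exons


class TestGenerateGenome:
    def test_tandem_arrays_adjacent_with_truth(self, genome, default_config):
        assert len(genome.truth.clusters) == len(default_config.tandem_array_spec)
        order = {}
        for m in genome.models:
            order.setdefault(m.location.chrom, []).append(m.gene_id)
        for members in genome.truth.clusters:
            chrom = next(
                m.location.chrom for m in genome.models if m.gene_id == members[0]
            )
            idx = [order[chrom].index(g) for g in members]
            assert idx == list(range(min(idx), min(idx) + len(members)))

    def test_pure_type2_mix(self):
        cfg = GeneratorConfig(
            seed=4, n_ltp_genes=12, type_mix=(("type2", 1.0),),
            tandem_array_spec=(), chrom_length_bp=20_000,
        )
        g = generate_genome(cfg)
        assert {t.ltp_type for t in g.truth.genes.values()} == {"type2"}

    def test_type_mix_within_multinomial_bounds(self):
        """Realized per-type counts over 200 seeds stay inside multinomial
        99% bounds of the configured mix."""
        from scipy.stats import binom

        cfg = GeneratorConfig()
        counts = {t: 0 for t, _ in cfg.type_mix}
        n_seeds, per_seed = 200, 50
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            for t in _sample_types(rng, cfg, per_seed):
                counts[t] += 1
        total = n_seeds * per_seed
        for t, p in cfg.type_mix:
            lo, hi = binom.ppf([0.005, 0.995], total, p)
            assert lo <= counts[t] <= hi, t

    def test_truth_matches_emitted_proteins(self, genome):
        for gid, truth in genome.truth.genes.items():
            protein = genome.proteins[gid]
            mature = protein[truth.signal_cleavage:
                             truth.gpi_omega if truth.gpi_omega else len(protein)]
            cys = tuple(i for i, r in enumerate(mature) if r == "C")
            assert cys == truth.cys_positions_mature

    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            GeneratorConfig(type_mix=(("type1", 0.5), ("type2", 0.4)))

    def test_sizing_error_when_genes_do_not_fit(self):
        with pytest.raises(ValueError, match="exceeding"):
            generate_genome(GeneratorConfig(seed=0, chrom_length_bp=2_000))

    def test_background_is_cysteine_codon_free(self, genome):
        gene_spans = {}
        for m in genome.models:
            gene_spans.setdefault(m.location.chrom, []).append(
                (m.location.start, m.location.end)
            )
        for chrom, seq in genome.chromosomes.items():
            mask = np.zeros(len(seq), bool)
            for s, e in gene_spans.get(chrom, []):
                mask[max(s - 2, 0) : e + 2] = True
            for i in range(len(seq) - 2):
                if not mask[i : i + 3].any():
                    assert seq[i : i + 3] not in ("TGT", "TGC")


class TestMutateCdsControlled:
    CDS = "AAA" * 10

    def test_zero_changes_identity(self):
        assert mutate_cds_controlled(self.CDS, 0, 0, seed=0) == self.CDS

    def test_single_synonymous_lysine_change(self):
        out = mutate_cds_controlled(self.CDS, 1, 0, seed=1)
        codons = [out[i : i + 3] for i in range(0, 30, 3)]
        assert codons.count("AAG") == 1 and codons.count("AAA") == 9

    @pytest.mark.parametrize("syn,nonsyn", [(0, 3), (4, 2), (2, 0)])
    def test_residue_diff_equals_nonsyn_count(self, syn, nonsyn):
        rng = np.random.default_rng(11)
        pool = "ADEFGHIKLMNQRSTVWY"
        for _ in range(10):
            protein = "".join(pool[i] for i in rng.integers(len(pool), size=60))
            cds = "".join(
                sorted(c for c, a in CODON_TO_AA.items() if a == r)[0] for r in protein
            )
            out = mutate_cds_controlled(cds, syn, nonsyn, seed=int(rng.integers(2**31)))
            assert len(out) == len(cds)
            diffs = sum(a != b for a, b in zip(translate(cds), translate(out)))
            assert diffs == nonsyn
            assert "*" not in translate(out)

    def test_insufficient_sites_reports_deficit(self):
        with pytest.raises(ValueError, match="insufficient"):
            mutate_cds_controlled("ATG", 5, 0, seed=0)


class TestGeneratePromoterSets:
    def test_full_frequency_plants_everywhere(self):
        spec = PromoterSpec(n_pos=10, n_neg=5, pos_freq=1.0, neg_freq=0.0, length=200)
        pos, neg, placements = generate_promoter_sets(spec, 1)
        planted = {(s, i) for s, i, _, _ in placements}
        for i, rec in enumerate(pos):
            assert ("pos", i) in planted
            assert "AGAAA" in rec.residues or "TTTCT" in rec.residues

    def test_seed_determinism(self):
        spec = PromoterSpec(n_pos=4, n_neg=4, length=150)
        a = generate_promoter_sets(spec, 9)
        b = generate_promoter_sets(spec, 9)
        assert [r.residues for r in a[0]] == [r.residues for r in b[0]]
        assert a[2] == b[2]

    def test_equal_frequencies_are_exchangeable(self):
        """With identical planting frequencies the per-promoter count
        distributions of the two sets are statistically indistinguishable."""
        from scipy.stats import mannwhitneyu

        from nsltp.promoter import KnownMotif, scan_motif

        motif = KnownMotif("m", "AGAAA")
        spec = PromoterSpec(n_pos=40, n_neg=40, pos_freq=0.5, neg_freq=0.5, length=500)
        counts_pos, counts_neg = [], []
        for seed in range(5):
            pos, neg, _ = generate_promoter_sets(spec, 100 + seed)
            counts_pos += [scan_motif(r.residues, motif) for r in pos]
            counts_neg += [scan_motif(r.residues, motif) for r in neg]
        _, p = mannwhitneyu(counts_pos, counts_neg)
        assert p > 0.01

    def test_non_acgt_motif_rejected(self):
        with pytest.raises(ValueError, match="ACGT"):
            PromoterSpec(motif="AGRAA")
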