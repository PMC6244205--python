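"""8CM grammar scanning, spacing signatures, CXC polarity and logo counts."""

import numpy as np
import pytest

from nsltp.core_io import SequenceRecord
from nsltp.motif_scan import (
    DEFAULT_GAP_BOUNDS,
    EightCMMatch,
    GapBounds,
    cxc_polarity,
    position_counts,
    scan_eight_cm,
    spacing_signature,
)

from .conftest import make_peptide
from .oracles import enumerate_8cm, resolve_overlaps


class TestScanEightCM:
    def test_type_c_pattern_single_match(self):
        pep = make_peptide((9, 14, 9, 12, 6))
        matches = scan_eight_cm(SequenceRecord.protein("p", pep))
        assert len(matches) == 1
        assert matches[0].gaps == (9, 14, 9, 12, 6)

    def test_seven_cysteines_no_match(self):
        pep = make_peptide((9, 14, 9, 12, 6)).replace("C", "", 1)
        assert scan_eight_cm(SequenceRecord.protein("p", pep)) == []

    def test_gap_outside_bounds_rejected(self):
        pep = make_peptide((2, 14, 9, 12, 6))  # g1=2 below min 3
        assert scan_eight_cm(SequenceRecord.protein("p", pep)) == []

    @pytest.mark.parametrize("n_extra_cys", [0, 3, 8])
    def test_equals_exhaustive_enumeration(self, n_extra_cys):
        """Scanner output matches brute-force enumeration over all cysteine
        8-tuples, with and without spurious extra cysteines."""
        rng = np.random.default_rng(42 + n_extra_cys)
        pool = "ADEFGHIKLMNPQRSTVWY"
        for _ in range(50):
            gaps = tuple(
                int(rng.integers(lo, hi + 1)) for lo, hi in DEFAULT_GAP_BOUNDS.as_tuple()
            )
            pep = list(make_peptide(
                gaps,
                nterm="".join(pool[i] for i in rng.integers(len(pool), size=rng.integers(0, 30))),
                cterm="".join(pool[i] for i in rng.integers(len(pool), size=rng.integers(0, 30))),
            ))
            for _ in range(n_extra_cys):
                pep[int(rng.integers(len(pep)))] = "C"
            pep = "".join(pep)[:400]
            rec = SequenceRecord.protein("p", pep)
            all_found = scan_eight_cm(rec, all_candidates=True)
            expect = enumerate_8cm(pep, DEFAULT_GAP_BOUNDS)
            assert [m.cys_positions for m in all_found] == expect
            resolved = scan_eight_cm(rec)
            assert [m.cys_positions for m in resolved] == resolve_overlaps(expect)

    def test_planted_recovery_on_default_genome(self, genome, identified):
        """Every planted motif is recovered with the generator's gap vector."""
        records, _ = identified
        assert len(records) == len(genome.truth.genes)
        for rec in records:
            truth = genome.truth.genes[rec.gene_id]
            assert rec.match.gaps == truth.gaps
            assert rec.match.cys_positions == truth.cys_positions_mature

    def test_match_invariants_enforced(self):
        with pytest.raises(ValueError):
            EightCMMatch("x", (0, 4, 9, 11, 20, 22, 30, 38), (3, 4, 8, 7, 7), "A")


class TestSpacingSignature:
    def _match(self, gaps):
        pep = make_peptide(gaps)
        return scan_eight_cm(SequenceRecord.protein("p", pep))[0]

    def test_type_c_g4_multiset(self):
        sigs = spacing_signature(
            {"typeC": [self._match((9, g2, 9, 12, 6)) for g2 in (14, 14, 19, 14, 19)]}
        )
        assert set(sigs["typeC"].gap_values[3]) == {12}
        assert sigs["typeC"].gap_values[1] == {14: 3, 19: 2}

    def test_single_match_echoes_gaps(self):
        sigs = spacing_signature({"typeD": [self._match((9, 14, 9, 11, 4))]})
        assert sigs["typeD"].render() == "CX9CX14CCX9CXCX11CX4C"

    def test_unique_values_flagged_across_types(self):
        sigs = spacing_signature(
            {
                "typeC": [self._match((9, 14, 9, 12, 6))],
                "type1": [self._match((9, 14, 9, 21, 7))],
            }
        )
        assert sigs["typeC"].unique_values[3] == {12}
        assert sigs["type1"].unique_values[3] == {21}
        assert sigs["typeC"].unique_values[0] == frozenset()

    def test_range_rendering_collapses_runs(self):
        sigs = spacing_signature(
            {"t": [self._match((9, g, 9, 12, 6)) for g in (13, 14, 15, 19)]}
        )
        assert "CX13-15,19CC" in sigs["t"].render()

    def test_empty_group(self):
        assert spacing_signature({"t": []})["t"].render() == ""


class TestCxcPolarity:
    def _match_with_x(self, x):
        pep = make_peptide((9, 14, 9, 12, 6)).replace("CAC", f"C{x}C", 1)
        (m,) = scan_eight_cm(SequenceRecord.protein("p", pep))
        assert m.cxc_x_residue == x
        return m

    def test_all_hydrophobic(self):
        frac = cxc_polarity({"t": [self._match_with_x("L")] * 3})
        assert frac["t"] == 1.0

    def test_half_hydrophobic(self):
        frac = cxc_polarity({"t": [self._match_with_x("L"), self._match_with_x("S")]})
        assert frac["t"] == 0.5

    def test_binomial_recovery_of_mixture(self):
        """Observed hydrophobic fraction falls in binomial 99% bounds of the
        residue mixture it was drawn from."""
        from scipy.stats import binom

        rng = np.random.default_rng(3)
        residues = "LS"  # hydrophobic mass 0.5
        n = 400
        matches = [self._match_with_x(residues[i]) for i in rng.integers(0, 2, n)]
        frac = cxc_polarity({"t": matches})["t"]
        lo, hi = binom.ppf([0.005, 0.995], n, 0.5) / n
        assert lo <= frac <= hi


class TestPositionCounts:
    def test_single_sequence_columns_sum_to_one(self):
        pep = make_peptide((9, 14, 9, 12, 6))
        (m,) = scan_eight_cm(SequenceRecord.protein("p", pep))
        pcm = position_counts([m], {"p": pep})
        assert (pcm.counts.sum(axis=1) == 1).all()

    def test_cysteine_columns_pure(self, genome, identified):
        records, _ = identified
        by_type = {}
        for r in records:
            by_type.setdefault(r.type, []).append(r)
        cys_idx = "ACDEFGHIKLMNPQRSTVWY".index("C")
        for t, recs in by_type.items():
            pcm = position_counts(
                [r.match for r in recs], {r.gene_id: r.mature_sequence for r in recs}
            )
            for label, row in zip(pcm.columns, pcm.counts):
                if label.startswith("C") and not label.startswith("CX"):
                    assert row.sum() == row[cys_idx] == len(recs)

    def test_gap_column_sums_match_coverage(self, genome, identified):
        """A gap column's count equals the number of sequences whose gap
        extends that far (left-aligned padding)."""
        records, _ = identified
        recs = [r for r in records if r.type == "type2"]
        pcm = position_counts(
            [r.match for r in recs], {r.gene_id: r.mature_sequence for r in recs}
        )
        gaps = [genome.truth.genes[r.gene_id].gaps for r in recs]
        for label, row in zip(pcm.columns, pcm.counts):
            if label.startswith("g"):
                g, j = label[1:].split(".")
                expect = sum(1 for gv in gaps if gv[int(g) - 1] >= int(j))
                assert row.sum() == expect
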