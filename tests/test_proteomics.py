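"""Identification criteria, localization calls, lysis QC, ranking, MW."""

import random

import pytest

from ghmine import annotation_screen as scr
from ghmine import proteomics as pr
from ghmine import synthetic_data as sd
from ghmine.io_formats import PELLET, SUPERNATANT, IdentificationRow


def ident(acc, fraction, count, unique=2, sample=None):
    return IdentificationRow(
        acc, fraction, sample or ("P1" if fraction == PELLET else "SN1"), count, unique
    )


def flag(acc, keywords=("amylase",), unannotated=False):
    return scr.CandidateFlag(acc, () if unannotated else tuple(keywords), (), unannotated)


class TestIdCriteria:
    def test_single_peptide_rows_dropped(self):
        rows = [ident("P1", SUPERNATANT, 5, unique=1), ident("P2", SUPERNATANT, 5, unique=2)]
        kept = pr.apply_id_criteria(rows)
        assert [r.protein_accession for r in kept] == ["P2"]

    def test_threshold_zero_is_identity(self):
        rows = [ident("P1", SUPERNATANT, 5, unique=0)]
        assert pr.apply_id_criteria(rows, 0) == rows

    def test_counts_sum_across_samples(self):
        rows = [
            ident("P1", SUPERNATANT, 4, sample="SN1"),
            ident("P1", SUPERNATANT, 6, sample="SN2"),
        ]
        assert pr.fraction_totals(rows)["P1"][SUPERNATANT] == 10


class TestLocalization:
    def test_pellet_only_is_intracellular(self):
        (call,) = pr.classify_localization([ident("P1", PELLET, 3)])
        assert call.call == pr.INTRACELLULAR and not call.in_both

    def test_both_fractions_is_secreted(self):
        (call,) = pr.classify_localization(
            [ident("P1", PELLET, 3), ident("P1", SUPERNATANT, 9)]
        )
        assert call.call == pr.SECRETED and call.in_both
        assert call.sup_count == 9 and call.pellet_count == 3

    def test_empty_input(self):
        assert pr.classify_localization([]) == []

    def test_partition_property(self, small_metagenome):
        """Secreted ∪ intracellular covers every identified protein once."""
        ids = sd.generate_identifications(small_metagenome.truth, sd.ExpressionSpec(seed=11))
        filtered = pr.apply_id_criteria(ids)
        calls = pr.classify_localization(filtered)
        assert len({c.protein_accession for c in calls}) == len(calls)
        assert {c.protein_accession for c in calls} == {
            r.protein_accession for r in filtered
        }


class TestLysisQC:
    def test_constructed_overlap_is_counted(self):
        """A pellet of 50 proteins of which 18 never reach the secretome."""
        rows = [ident(f"P{i:02d}", PELLET, 100 - i) for i in range(50)]
        rows += [ident(f"P{i:02d}", SUPERNATANT, 5) for i in range(18, 50)]
        report = pr.lysis_qc(rows, descriptions={})
        assert report.top_k == 50
        assert report.absent_from_secretome == 18

    def test_no_leak_means_no_markers(self, small_metagenome):
        ids = sd.generate_identifications(
            small_metagenome.truth, sd.ExpressionSpec(lysis_rate=0.0, seed=11)
        )
        descriptions = {p.accession: p.description for p in small_metagenome.proteins}
        report = pr.lysis_qc(pr.apply_id_criteria(ids), descriptions)
        assert all(count == 0 for count in report.marker_hits.values())

    def test_top_k_capped_at_pellet_size(self):
        rows = [ident(f"P{i}", PELLET, 10) for i in range(5)]
        report = pr.lysis_qc(rows, descriptions={}, top_k=50)
        assert report.top_k == 5

    def test_nonpositive_top_k_is_error(self):
        with pytest.raises(ValueError):
            pr.lysis_qc([ident("P1", PELLET, 3)], {}, top_k=0)


class TestRankCandidates:
    def test_ties_break_by_accession(self):
        flags = [flag("B"), flag("A")]
        calls = pr.classify_localization(
            [ident("A", SUPERNATANT, 9), ident("B", SUPERNATANT, 9)]
        )
        records = pr.rank_candidates(flags, calls, SUPERNATANT)
        assert [(r.protein_accession, r.rank) for r in records] == [("A", 1), ("B", 2)]

    def test_zero_candidates(self):
        calls = pr.classify_localization([ident("X", SUPERNATANT, 5)])
        assert pr.rank_candidates([], calls, SUPERNATANT) == []

    def test_unknown_fraction_is_error(self):
        with pytest.raises(ValueError):
            pr.rank_candidates([], [], "membrane")

    def test_non_candidates_excluded(self):
        flags = [flag("A", keywords=())]  # annotated, no keyword hits
        calls = pr.classify_localization([ident("A", SUPERNATANT, 5)])
        assert pr.rank_candidates(flags, calls, SUPERNATANT) == []

    def test_permutation_invariance(self, small_metagenome):
        ids = sd.generate_identifications(small_metagenome.truth, sd.ExpressionSpec(seed=11))
        flags = scr.screen(small_metagenome.annotations, small_metagenome.proteins)
        filtered = pr.apply_id_criteria(ids)
        shuffled = list(filtered)
        random.Random(5).shuffle(shuffled)
        a = pr.rank_candidates(flags, pr.classify_localization(filtered), SUPERNATANT)
        b = pr.rank_candidates(flags, pr.classify_localization(shuffled), SUPERNATANT)
        assert a == b

    def test_fixture_secretome_report(self, secretome_table):
        flags = scr.screen(secretome_table.annotations, secretome_table.proteins)
        calls = pr.classify_localization(pr.apply_id_criteria(secretome_table.identifications))
        records = pr.rank_candidates(
            flags, calls, SUPERNATANT, molecular_weights=secretome_table.molecular_weights
        )
        assert len(records) == 17
        assert all(r.localization == pr.SECRETED for r in records)
        ranks = [r.rank for r in records]
        assert ranks == list(range(1, 18))


class TestMolecularWeight:
    @pytest.mark.parametrize(
        "sequence,expected",
        [("G", 75.07), ("", 18.02), ("GG", 132.12)],
    )
    def test_average_mass_oracle_values(self, sequence, expected):
        """Frozen from the standard average residue-mass table:
        glycine residue 57.05 Da + one water 18.02 Da per chain."""
        assert pr.compute_molecular_weight(sequence) == pytest.approx(expected, abs=0.01)

    def test_unknown_residue_is_error(self):
        with pytest.raises(ValueError):
            pr.compute_molecular_weight("GXG")

    def test_additivity(self):
        """MW of a concatenation = sum of parts minus one water."""
        a, b = "MKVLA", "GDEW"
        assert pr.compute_molecular_weight(a + b) == pytest.approx(
            pr.compute_molecular_weight(a) + pr.compute_molecular_weight(b) - pr.WATER_MASS,
            abs=1e-6,
        )
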