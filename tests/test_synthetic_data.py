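"""Generator properties: reproducibility, ground-truth consistency,
scenario statistics, and the packaged worked-example fixture."""

import numpy as np
import pytest

from ghmine import annotation_screen as scr
from ghmine import proteomics as pr
from ghmine import synthetic_data as sd
from ghmine import taxonomy as tx
from ghmine.io_formats import PELLET, SUPERNATANT


class TestReproducibility:
    def test_identical_seed_byte_identical_files(self, tmp_path):
        for run in ("a", "b"):
            sd.generate_dataset(tmp_path / run, n_orfs=100, seed=9)
        for name in (
            "proteins.faa",
            "annotations.tsv",
            "alignments.tsv",
            "identifications.tsv",
            "ground_truth.json",
        ):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_different_seeds_differ(self, tmp_path):
        sd.generate_dataset(tmp_path / "a", n_orfs=100, seed=1)
        sd.generate_dataset(tmp_path / "b", n_orfs=100, seed=2)
        assert (tmp_path / "a" / "proteins.faa").read_bytes() != (
            tmp_path / "b" / "proteins.faa"
        ).read_bytes()


class TestMetagenome:
    def test_truth_matches_emitted_objects(self, small_metagenome):
        accessions = {p.accession for p in small_metagenome.proteins}
        assert set(small_metagenome.truth.orfs) == accessions
        annotated = {a.protein_accession for a in small_metagenome.annotations}
        for accession, truth in small_metagenome.truth.orfs.items():
            assert (accession in annotated) == truth.annotated
        assert small_metagenome.truth.planted_top_secreted in accessions

    def test_high_unclassifiable_fraction_reflected_in_consensus(self):
        """With 80% lineage-free ORFs, roughly 80% stay unassigned at genus."""
        community = sd.inoculum_community(n_orfs=600, seed=2)
        mg = sd.generate_metagenome(community)
        lineages = tx.classify_all(mg.alignments)
        unassigned = sum(1 for lin in lineages.values() if lin.genus is None) / len(lineages)
        assert unassigned == pytest.approx(0.8, abs=0.05)

    def test_inoculum_has_many_genera(self):
        community = sd.inoculum_community(n_orfs=2000, seed=4)
        mg = sd.generate_metagenome(community)
        assert len({t.genus for t in mg.truth.orfs.values()}) > 100

    def test_gh_fraction_zero_leaves_only_unannotated_candidates(self):
        community = sd.enrichment_community(n_orfs=200, seed=6)
        mg = sd.generate_metagenome(community, gh_fraction=0.0)
        flags = scr.screen(mg.annotations, mg.proteins)
        for f in flags:
            if f.is_candidate:
                assert f.is_unannotated


class TestIdentifications:
    def test_no_lysis_keeps_intracellular_roles_out_of_supernatant(self, small_metagenome):
        ids = sd.generate_identifications(
            small_metagenome.truth, sd.ExpressionSpec(lysis_rate=0.0, seed=11)
        )
        for row in ids:
            if row.fraction == SUPERNATANT:
                assert small_metagenome.truth.orfs[row.protein_accession].role == sd.SECRETED_GH

    def test_planted_gene_tops_secreted_report(self, small_metagenome):
        ids = sd.generate_identifications(small_metagenome.truth, sd.ExpressionSpec(seed=11))
        flags = scr.screen(small_metagenome.annotations, small_metagenome.proteins)
        calls = pr.classify_localization(pr.apply_id_criteria(ids))
        records = pr.rank_candidates(flags, calls, SUPERNATANT)
        assert records[0].protein_accession == small_metagenome.truth.planted_top_secreted

    def test_rows_satisfy_identification_invariants(self, small_metagenome):
        ids = sd.generate_identifications(small_metagenome.truth, sd.ExpressionSpec(seed=3))
        assert ids
        for row in ids:
            assert row.spectral_count >= row.unique_peptides >= 0
            assert row.fraction in (PELLET, SUPERNATANT)

    def test_composition_estimate_tightens_with_depth(self):
        """The dominant-genus spectral share converges on the target as
        sequencing/identification depth grows."""
        deviations = {}
        for depth in (500, 20000):
            devs = []
            for seed in (0, 1, 2):
                community = sd.enrichment_community(n_orfs=1000, seed=seed)
                mg = sd.generate_metagenome(community)
                ids = sd.generate_identifications(
                    mg.truth, sd.ExpressionSpec(seed=seed), depth=depth
                )
                lineages = tx.classify_all(mg.alignments)
                table = tx.genus_composition(ids, lineages)
                devs.append(abs(table.entries.get("Alicyclobacillus", 0.0) - 70.0))
            deviations[depth] = float(np.mean(devs))
        assert deviations[500] < 15.0
        assert deviations[20000] < 5.0


class TestSecretomeFixture:
    def test_gh13_flagship_row(self, secretome_table):
        rows = [a for a in secretome_table.annotations if a.protein_accession == "MMBJNONL_14124"]
        assert secretome_table.molecular_weights["MMBJNONL_14124"] == 140550
        assert {r.entry_id for r in rows} == {"IPR006047", "IPR004185", "IPR017853"}

    def test_six_annotated_rows(self, secretome_table):
        annotated = {a.protein_accession for a in secretome_table.annotations if a.entry_id}
        assert len(annotated) == 6

    def test_unannotated_row(self, secretome_table):
        assert secretome_table.molecular_weights["MMBJNONL_02999"] == 13289
        assert not any(
            a.protein_accession == "MMBJNONL_02999" for a in secretome_table.annotations
        )

    def test_all_present_in_supernatant_with_peptide_evidence(self, secretome_table):
        assert len(secretome_table.identifications) == 17
        for row in secretome_table.identifications:
            assert row.fraction == SUPERNATANT
            assert row.unique_peptides >= 2

    def test_fixture_files_round_trip(self, tmp_path, secretome_table):
        paths = secretome_table.write(tmp_path)
        assert all(p.exists() for p in paths.values())
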