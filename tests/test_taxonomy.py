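"""Consensus-lineage voting and spectral-count community composition."""

import random

import pytest

from ghmine import synthetic_data as sd
from ghmine import taxonomy as tx
from ghmine.io_formats import AlignmentRow, IdentificationRow


def hit(query="Q", subject="S", bitscore=100.0, lineage=""):
    return AlignmentRow(
        query_accession=query,
        subject_accession=subject,
        pct_identity=90.0,
        align_length=100,
        bitscore=bitscore,
        evalue=1e-20,
        subject_lineage=lineage,
    )


def ident(acc, count, fraction="pellet", sample="P1"):
    return IdentificationRow(acc, fraction, sample, count, min(count, 2))


LIN_A = "Bacteria;P;C;O;F;A;A sp."
LIN_B = "Bacteria;P;C;O;F;B;B sp."


class TestConsensusLineage:
    def test_unanimous_hits_assign_genus(self):
        hits = [hit(subject=f"S{i}", lineage=LIN_A) for i in range(25)]
        assert tx.consensus_lineage(hits).genus == "A"

    def test_no_hits_fully_unassigned(self):
        assert tx.consensus_lineage([]) == tx.Lineage.unassigned()

    def test_split_vote_strict_majority(self):
        """Genera A/B/B at bitscores 100/60/50 share family F: the top
        hit's genus A holds only 100/210 < 0.5 of the mass, but B holds
        110/210 > 0.5 and wins; family F is unanimous."""
        hits = [
            hit(subject="S1", bitscore=100, lineage=LIN_A),
            hit(subject="S2", bitscore=60, lineage=LIN_B),
            hit(subject="S3", bitscore=50, lineage=LIN_B),
        ]
        lineage = tx.consensus_lineage(hits)
        assert lineage.ranks[4] == "F"
        assert lineage.genus == "B"
        assert 100 / 210 <= 0.5  # the top hit alone cannot carry the rank

    def test_even_split_leaves_rank_unassigned(self):
        hits = [
            hit(subject="S1", bitscore=50, lineage=LIN_A),
            hit(subject="S2", bitscore=50, lineage=LIN_B),
        ]
        lineage = tx.consensus_lineage(hits)
        assert lineage.genus is None
        assert lineage.ranks[4] == "F"  # shared prefix still assigned

    def test_lineage_free_hits_dilute_support(self):
        hits = [
            hit(subject="S1", bitscore=100, lineage=LIN_A),
            hit(subject="S2", bitscore=100, lineage=""),
            hit(subject="S3", bitscore=100, lineage=""),
        ]
        assert tx.consensus_lineage(hits) == tx.Lineage.unassigned()

    def test_truncation_to_top_n(self):
        strong = [hit(subject=f"A{i}", bitscore=500 - i, lineage=LIN_A) for i in range(25)]
        weak = [hit(subject=f"B{i}", bitscore=10, lineage=LIN_B) for i in range(50)]
        assert tx.consensus_lineage(strong + weak).genus == "A"

    def test_mixed_queries_rejected(self):
        with pytest.raises(ValueError):
            tx.consensus_lineage([hit(query="Q1"), hit(query="Q2")])

    def test_prefix_property_enforced(self):
        with pytest.raises(ValueError):
            tx.Lineage(("Bacteria", None, "C", None, None, None, None))

    def test_brute_force_equivalence_on_small_hit_sets(self):
        """The implementation equals an exhaustive rank-by-rank weighted
        voter on every subset of size <= 6 of a conflicted hit pool."""
        lineages = [
            LIN_A,
            LIN_B,
            "Bacteria;P;C;O;F2;X;X sp.",
            "Bacteria;P2",
            "",
            "Archaea;AP;AC;AO;AF;AG;AG sp.",
        ]
        rng = random.Random(42)
        pool = [
            hit(subject=f"S{i}", bitscore=rng.randint(10, 500), lineage=rng.choice(lineages))
            for i in range(6)
        ]

        def brute_force(subset):
            total = sum(h.bitscore for h in subset)
            ranks = []
            for level in range(7):
                best = None
                names = {
                    tx.Lineage.from_string(h.subject_lineage).ranks[level]
                    for h in subset
                } - {None}
                for name in sorted(names):
                    mass = sum(
                        h.bitscore
                        for h in subset
                        if tx.Lineage.from_string(h.subject_lineage).ranks[level] == name
                    )
                    if mass / total > 0.5:
                        best = name
                if best is None:
                    break
                ranks.append(best)
            ranks += [None] * (7 - len(ranks))
            return tuple(ranks)

        for mask in range(1, 2 ** len(pool)):
            subset = [h for i, h in enumerate(pool) if mask >> i & 1]
            assert tx.consensus_lineage(subset).ranks == brute_force(subset), subset

    def test_support_is_monotone_down_the_ranks(self):
        """For any hit set, the winning-mass fraction never increases with
        depth, so a lineage never 'recovers' after an unassigned rank."""
        rng = random.Random(7)
        lineages = [LIN_A, LIN_B, "Bacteria;P;C2;O2;F2;G2;G2 sp.", ""]
        for _ in range(50):
            hits = [
                hit(subject=f"S{i}", bitscore=rng.randint(1, 300), lineage=rng.choice(lineages))
                for i in range(rng.randint(1, 8))
            ]
            total = sum(h.bitscore for h in hits)
            parsed = [tx.Lineage.from_string(h.subject_lineage) for h in hits]
            prev = 1.0
            for level in range(7):
                masses = {}
                for lineage, h in zip(parsed, hits):
                    if lineage.ranks[level] is not None:
                        masses[lineage.ranks[level]] = masses.get(lineage.ranks[level], 0) + h.bitscore
                top = max(masses.values(), default=0) / total
                assert top <= prev + 1e-12
                prev = top


class TestClassifyAll:
    def test_disjoint_queries(self):
        rows = [hit(query="Q1", lineage=LIN_A), hit(query="Q2", lineage=LIN_B)]
        result = tx.classify_all(rows)
        assert set(result) == {"Q1", "Q2"}
        assert result["Q1"].genus == "A" and result["Q2"].genus == "B"

    def test_row_order_invariance(self, small_metagenome):
        rows = list(small_metagenome.alignments)
        shuffled = list(rows)
        random.Random(3).shuffle(shuffled)
        assert tx.classify_all(rows) == tx.classify_all(shuffled)

    def test_noise_free_generator_recovery(self):
        """50 ORFs with clean hits: every true genus recovered."""
        community = sd.enrichment_community(
            n_orfs=50, unclassifiable_fraction=0.0, seed=3
        )
        mg = sd.generate_metagenome(community, contamination_rate=0.0)
        lineages = tx.classify_all(mg.alignments)
        assert all(
            lineages[acc].genus == truth.genus for acc, truth in mg.truth.orfs.items()
        )


class TestGenusComposition:
    def test_single_genus_is_100(self):
        lineages = {"P1": tx.Lineage.from_string(LIN_A), "P2": tx.Lineage.from_string(LIN_A)}
        table = tx.genus_composition([ident("P1", 10), ident("P2", 5)], lineages)
        assert table.entries == {"A": 100.0}

    def test_direct_ratio(self):
        lineages = {"X": tx.Lineage.from_string("B;P;C;O;F;X"), "Y": tx.Lineage.from_string("B;P;C;O;F;Y")}
        table = tx.genus_composition([ident("X", 70), ident("Y", 30)], lineages)
        assert table.entries["X"] == pytest.approx(70.0)

    def test_missing_lineage_goes_unclassified(self):
        table = tx.genus_composition([ident("P1", 4)], {})
        assert table.entries == {tx.UNCLASSIFIED: 100.0}

    def test_zero_counts_error(self):
        with pytest.raises(ValueError):
            tx.genus_composition([ident("P1", 0)], {})

    def test_permutation_invariance_and_closure(self):
        lineages = {
            f"P{i}": tx.Lineage.from_string(f"B;P;C;O;F;G{i % 3}") for i in range(9)
        }
        rows = [ident(f"P{i}", i + 1) for i in range(9)]
        forward = tx.genus_composition(rows, lineages)
        backward = tx.genus_composition(list(reversed(rows)), lineages)
        assert forward.entries == backward.entries
        assert sum(forward.entries.values()) == pytest.approx(100.0, abs=1e-9)
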