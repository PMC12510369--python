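"""Consensus-lineage classification and genus composition of both communities.

Reads the datasets written by 01_simulate_communities.py, assigns every
ORF a bitscore-consensus lineage from its alignment hits, and reports
(a) how many ORFs remain unclassified at genus rank and (b) the
spectral-count-weighted genus composition of the enrichment.

Writes results/tables/{scenario}_lineages.tsv and
results/tables/enrichment_composition.tsv.
"""

import sys
from pathlib import Path

from ghmine import io_formats as io
from ghmine import taxonomy as tx

DATA = Path("results/data")
OUT = Path("results/tables")


def main() -> None:
    if not DATA.exists():
        sys.exit("run analysis/01_simulate_communities.py first")
    OUT.mkdir(parents=True, exist_ok=True)
    for scenario in ("inoculum", "enrichment"):
        alignments, _ = io.read_alignment_tsv(DATA / scenario / "alignments.tsv")
        lineages = tx.classify_all(alignments)
        tx.write_lineage_tsv(lineages, OUT / f"{scenario}_lineages.tsv")
        unassigned = sum(1 for lin in lineages.values() if lin.genus is None)
        genera = {lin.genus for lin in lineages.values()} - {None}
        print(
            f"{scenario}: {len(lineages)} ORFs classified; {len(genera)} genera; "
            f"{100 * unassigned / len(lineages):.1f}% unassigned at genus rank"
        )
        if scenario == "enrichment":
            ids = io.read_identifications(DATA / scenario / "identifications.tsv")
            table = tx.genus_composition(ids, lineages)
            tx.write_composition_tsv(table, OUT / "enrichment_composition.tsv")
            top_genus, share = max(table.entries.items(), key=lambda kv: kv[1])
            print(f"  dominant genus by spectral counts: {top_genus} at {share:.1f}%")


if __name__ == "__main__":
    main()
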