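"""Keyword screen of the enrichment metagenome for GH13/GH57 candidates.

Flags every ORF whose annotations mention the starch/pullulan-active
keyword set (family 13, GH13, family 57, GH57, amylase, glycosidase,
glycoside hydrolase, pullulan) and retains unannotated ORFs as
candidates for novel sequences.  Writes
results/tables/enrichment_candidate_flags.tsv.
"""

import sys
from pathlib import Path

from ghmine import annotation_screen as scr
from ghmine import io_formats as io

DATA = Path("results/data/enrichment")
OUT = Path("results/tables")


def main() -> None:
    if not DATA.exists():
        sys.exit("run analysis/01_simulate_communities.py first")
    OUT.mkdir(parents=True, exist_ok=True)
    proteins = io.read_protein_fasta(DATA / "proteins.faa")
    annotations, _ = io.read_annotation_tsv(DATA / "annotations.tsv")
    flags = scr.screen(annotations, proteins)
    scr.write_flags_tsv(flags, OUT / "enrichment_candidate_flags.tsv")
    keyword_hits = sum(bool(f.matched_keywords) for f in flags)
    unannotated = sum(f.is_unannotated for f in flags)
    print(
        f"{len(proteins)} ORFs screened: {keyword_hits} keyword-flagged, "
        f"{unannotated} unannotated (retained), "
        f"{keyword_hits + unannotated} candidates total"
    )
    family13 = scr.restrict_to_family(flags, ("family 13", "GH13"))
    print(f"of the keyword-flagged, {len(family13)} carry a family-13 signature")


if __name__ == "__main__":
    main()
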