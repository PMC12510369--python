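"""Keyword screen over functional annotations.

Candidate glycoside-hydrolase genes are flagged by a case-insensitive
substring search of a keyword list against every annotation field of a
protein (signature id/description and integrated-entry id/description).
Proteins with no annotation rows at all are retained as candidates too,
so completely novel sequences are not lost — the screen can only ever
narrow at the expression/localization stage, never here.

The default keyword list targets starch/pullulan-active enzymes of the
α-amylase superfamily (GH13) and the GH57 family.
"""

from __future__ import annotations

import logging
import unicodedata
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_formats import AnnotationRow, ProteinEntry

logger = logging.getLogger("ghmine.screen")

DEFAULT_KEYWORDS = (
    "family 13",
    "GH13",
    "family 57",
    "GH57",
    "amylase",
    "glycosidase",
    "glycoside hydrolase",
    "pullulan",
)


def _fold(text: str) -> str:
    """NFC-normalize then casefold, so Greek letters and commas match verbatim."""
    return unicodedata.normalize("NFC", text).casefold()


@dataclass(frozen=True)
class KeywordSet:
    """Ordered, duplicate-free (after case folding) search strings."""

    keywords: tuple[str, ...] = DEFAULT_KEYWORDS

    def __post_init__(self) -> None:
        if not self.keywords:
            raise ValueError("keyword set must be non-empty")
        folded = [_fold(k) for k in self.keywords]
        if len(set(folded)) != len(folded):
            raise ValueError("duplicate keywords after case folding")


@dataclass(frozen=True)
class CandidateFlag:
    """Screen verdict for one protein."""

    protein_accession: str
    matched_keywords: tuple[str, ...]
    matched_signatures: tuple[str, ...]
    is_unannotated: bool

    def __post_init__(self) -> None:
        if self.is_unannotated and self.matched_keywords:
            raise ValueError("unannotated protein cannot have keyword matches")

    @property
    def is_candidate(self) -> bool:
        return bool(self.matched_keywords) or self.is_unannotated


def screen(
    annotations: Iterable[AnnotationRow],
    proteins: Sequence[ProteinEntry],
    keywords: KeywordSet = KeywordSet(),
    unannotated_means_no_entry: bool = False,
) -> list[CandidateFlag]:
    """Flag candidates by keyword search; retain unannotated proteins.

    Every input protein yields exactly one flag, in input order.
    Annotation rows referencing accessions absent from ``proteins`` are
    logged and ignored.  ``unannotated_means_no_entry`` switches the
    stricter reading of "unannotated" — no *integrated* entry rather
    than no annotation row at all (default off).
    """
    known = {p.accession for p in proteins}
    rows_by_protein: dict[str, list[AnnotationRow]] = {acc: [] for acc in known}
    n_orphans = 0
    for row in annotations:
        if row.protein_accession not in known:
            n_orphans += 1
            continue
        rows_by_protein[row.protein_accession].append(row)
    if n_orphans:
        logger.warning("%d annotation rows reference unknown proteins; ignored", n_orphans)

    folded_keywords = [(_fold(k), k) for k in keywords.keywords]
    flags: list[CandidateFlag] = []
    for protein in proteins:
        rows = rows_by_protein[protein.accession]
        if unannotated_means_no_entry:
            unannotated = all(r.entry_id is None for r in rows)
        else:
            unannotated = not rows
        matched: list[str] = []
        signatures: list[str] = []
        for folded, keyword in folded_keywords:
            hit_ids = [
                r.signature_id
                for r in rows
                if any(
                    folded in _fold(text)
                    for text in (r.signature_desc, r.entry_desc or "", r.signature_id, r.entry_id or "")
                )
            ]
            if hit_ids:
                matched.append(keyword)
                signatures.extend(s for s in hit_ids if s not in signatures)
        flags.append(
            CandidateFlag(
                protein_accession=protein.accession,
                matched_keywords=tuple(matched) if not unannotated else (),
                matched_signatures=tuple(signatures) if not unannotated else (),
                is_unannotated=unannotated,
            )
        )
    return flags


def restrict_to_family(
    flags: Iterable[CandidateFlag], family_keywords: Iterable[str]
) -> list[CandidateFlag]:
    """Retain flags matching at least one family keyword; unannotated excluded."""
    family = {_fold(k) for k in family_keywords}
    return [
        f
        for f in flags
        if not f.is_unannotated and family & {_fold(k) for k in f.matched_keywords}
    ]


def write_flags_tsv(flags: Iterable[CandidateFlag], path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("accession\tmatched_keywords\tmatched_signatures\tis_unannotated\n")
        for f in flags:
            handle.write(
                f"{f.protein_accession}\t{';'.join(f.matched_keywords)}\t"
                f"{';'.join(f.matched_signatures)}\t{str(f.is_unannotated).lower()}\n"
            )
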