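"""Integration of fractionated metaproteomics with the annotation screen.

The secretome (culture supernatant) and the cell pellet are analysed as
separate fractions.  A protein passing the identification criteria in at
least one supernatant sample is called *secreted* — secreted enzymes can
also be cell-associated, so pellet co-detection does not revoke the call
(a ``both`` sub-label is kept for QC).  Proteins identified only in the
pellet are *intracellular*.  Candidate ranking is by summed spectral
count in the fraction that defines the localization class.

The lysis QC asks whether supernatant identifications could be cytoplasm
from dead cells: it takes the top-k most abundant pellet proteins, counts
how many were never seen in the supernatant, and looks for abundant
glycolytic markers in the secretome.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from Bio.Data.IUPACData import protein_weights

from .annotation_screen import CandidateFlag
from .io_formats import PELLET, SUPERNATANT, IdentificationRow

logger = logging.getLogger("ghmine.proteomics")

WATER_MASS = 18.0153  # average mass of H2O, Da

SECRETED = "secreted"
INTRACELLULAR = "intracellular"

#: Abundant glycolytic enzymes expected to stay intracellular; their
#: appearance in the secretome indicates cell lysis.
DEFAULT_MARKERS = (
    "glyceraldehyde-3-phosphate dehydrogenase",
    "phosphoglycerate mutase",
    "glucose-6-phosphate isomerase",
)


@dataclass(frozen=True)
class LocalizationCall:
    protein_accession: str
    call: str  # secreted | intracellular
    sup_count: int
    pellet_count: int
    in_both: bool = False

    def __post_init__(self) -> None:
        if self.call not in (SECRETED, INTRACELLULAR):
            raise ValueError(f"unknown localization {self.call!r}")


@dataclass(frozen=True)
class LysisQCReport:
    top_k: int
    absent_from_secretome: int
    marker_hits: Mapping[str, int]  # marker name -> secretome spectral count (0 = absent)
    markers: tuple[str, ...] = DEFAULT_MARKERS

    def __post_init__(self) -> None:
        if not (0 <= self.absent_from_secretome <= self.top_k):
            raise ValueError("absent_from_secretome outside [0, top_k]")


@dataclass(frozen=True)
class CandidateRecord:
    """One row of the final candidate report."""

    protein_accession: str
    molecular_weight: Optional[float]
    entry_ids: tuple[str, ...]
    entry_descs: tuple[str, ...]
    matched_keywords: tuple[str, ...]
    localization: str
    sup_count: int
    pellet_count: int
    rank: int


def apply_id_criteria(
    ids: Iterable[IdentificationRow], min_unique_peptides: int = 2
) -> list[IdentificationRow]:
    """Keep rows with at least ``min_unique_peptides`` unique peptides.

    FDR control is the search engine's job and is assumed applied
    upstream; only the unique-peptide identification criterion is
    enforced here.  Threshold 0 is the identity filter.
    """
    return [r for r in ids if r.unique_peptides >= min_unique_peptides]


def fraction_totals(ids: Iterable[IdentificationRow]) -> dict[str, dict[str, int]]:
    """Per-protein spectral-count totals summed across samples, per fraction."""
    totals: dict[str, dict[str, int]] = defaultdict(lambda: {PELLET: 0, SUPERNATANT: 0})
    for row in ids:
        totals[row.protein_accession][row.fraction] += row.spectral_count
    return dict(totals)


def classify_localization(filtered_ids: Iterable[IdentificationRow]) -> list[LocalizationCall]:
    """One call per identified protein: supernatant presence ⇒ secreted,
    pellet-only ⇒ intracellular.  The two classes partition the set."""
    totals = fraction_totals(filtered_ids)
    present: dict[str, set[str]] = defaultdict(set)
    for row in filtered_ids:
        present[row.protein_accession].add(row.fraction)
    calls = []
    for accession in sorted(totals):
        fractions = present[accession]
        call = SECRETED if SUPERNATANT in fractions else INTRACELLULAR
        calls.append(
            LocalizationCall(
                protein_accession=accession,
                call=call,
                sup_count=totals[accession][SUPERNATANT],
                pellet_count=totals[accession][PELLET],
                in_both=len(fractions) == 2,
            )
        )
    return calls


def lysis_qc(
    filtered_ids: Sequence[IdentificationRow],
    descriptions: Mapping[str, str],
    top_k: int = 50,
    markers: Sequence[str] = DEFAULT_MARKERS,
) -> LysisQCReport:
    """Cytoplasmic-contamination check on the secretome.

    ``descriptions`` maps accession → protein description; markers are
    matched by case-insensitive substring against it.  ``top_k`` larger
    than the pellet uses the whole pellet with a warning.
    """
    if top_k <= 0:
        raise ValueError("top_k must be positive")
    totals = fraction_totals(filtered_ids)
    pellet = [(acc, t[PELLET]) for acc, t in totals.items() if t[PELLET] > 0]
    if not pellet:
        raise ValueError("lysis QC needs at least one pellet protein")
    if top_k > len(pellet):
        logger.warning("top_k=%d exceeds pellet size %d; using full pellet", top_k, len(pellet))
    top = sorted(pellet, key=lambda kv: (-kv[1], kv[0]))[:top_k]
    in_secretome = {
        r.protein_accession for r in filtered_ids if r.fraction == SUPERNATANT
    }
    absent = sum(1 for acc, _ in top if acc not in in_secretome)

    marker_hits: dict[str, int] = {}
    for marker in markers:
        count = 0
        needle = marker.casefold()
        for acc in in_secretome:
            if needle in descriptions.get(acc, "").casefold():
                count += totals[acc][SUPERNATANT]
        marker_hits[marker] = count
    return LysisQCReport(
        top_k=min(top_k, len(pellet)),
        absent_from_secretome=absent,
        marker_hits=marker_hits,
        markers=tuple(markers),
    )


def rank_candidates(
    flags: Sequence[CandidateFlag],
    calls: Sequence[LocalizationCall],
    fraction: str,
    molecular_weights: Optional[Mapping[str, float]] = None,
    entries: Optional[Mapping[str, Sequence[tuple[str, str]]]] = None,
) -> list[CandidateRecord]:
    """Candidates ∩ localization class, ranked by defining-fraction abundance.

    ``fraction`` is "supernatant" (secreted class) or "pellet"
    (intracellular class).  Ties in spectral count break by accession
    ascending so the report is a strict total order.  ``entries`` maps
    accession → sequence of (entry_id, entry_desc) pairs for the report.
    """
    if fraction == SUPERNATANT:
        wanted, key = SECRETED, lambda c: c.sup_count
    elif fraction == PELLET:
        wanted, key = INTRACELLULAR, lambda c: c.pellet_count
    else:
        raise ValueError(f"unknown fraction {fraction!r}")
    flag_by_acc = {f.protein_accession: f for f in flags}
    chosen = [
        c
        for c in calls
        if c.call == wanted
        and c.protein_accession in flag_by_acc
        and flag_by_acc[c.protein_accession].is_candidate
    ]
    chosen.sort(key=lambda c: (-key(c), c.protein_accession))
    records = []
    for rank, call in enumerate(chosen, 1):
        flag = flag_by_acc[call.protein_accession]
        pairs = tuple((entries or {}).get(call.protein_accession, ()))
        records.append(
            CandidateRecord(
                protein_accession=call.protein_accession,
                molecular_weight=(molecular_weights or {}).get(call.protein_accession),
                entry_ids=tuple(dict.fromkeys(p[0] for p in pairs)),
                entry_descs=tuple(dict.fromkeys(p[1] for p in pairs)),
                matched_keywords=flag.matched_keywords,
                localization=call.call,
                sup_count=call.sup_count,
                pellet_count=call.pellet_count,
                rank=rank,
            )
        )
    return records


def compute_molecular_weight(sequence: str) -> float:
    """Average (not monoisotopic) molecular weight of a peptide in Da.

    Sum of free amino-acid average masses minus one water per peptide
    bond; the empty chain is one water.  'X' and other non-canonical
    residues have no defined average mass and are an error.
    """
    mass = WATER_MASS
    for residue in sequence:
        try:
            mass += protein_weights[residue] - WATER_MASS
        except KeyError:
            raise ValueError(f"no average mass for residue {residue!r}") from None
    return mass
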