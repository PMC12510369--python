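"""Bitscore-consensus taxonomic classification of ORFs.

Each ORF's alignment hits carry a semicolon-delimited subject lineage
(superkingdom down to species, possibly truncated).  The consensus
lineage is a rank-wise weighted vote over the top hits: at each rank,
a name is accepted only if the hits carrying it hold a strict majority
of the retained bitscore mass; the first rank without a majority name
ends the lineage (prefix property).  This degrades gracefully under
conflicting hits — an LCA-like behaviour — and, with unanimous hits,
returns the full shared lineage.

Community composition is spectral-count weighted: the share of a genus
is the summed spectral counts of proteins assigned to it over the grand
total, normalized to 100%, with an explicit "unclassified" bucket.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .io_formats import AlignmentRow, IdentificationRow

RANKS = ("superkingdom", "phylum", "class", "order", "family", "genus", "species")
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class Lineage:
    """Ranked taxonomy; unassigned ranks are None, and once a rank is
    unassigned every deeper rank is too."""

    ranks: tuple[Optional[str], ...]

    def __post_init__(self) -> None:
        if len(self.ranks) != len(RANKS):
            raise ValueError(f"lineage must have {len(RANKS)} ranks")
        seen_gap = False
        for name in self.ranks:
            if name is None:
                seen_gap = True
            elif seen_gap:
                raise ValueError("lineage violates prefix property")

    @classmethod
    def unassigned(cls) -> "Lineage":
        return cls((None,) * len(RANKS))

    @classmethod
    def from_string(cls, lineage: str) -> "Lineage":
        """Parse 'Bacteria;Bacillota;...' (≤7 ranks, may truncate)."""
        names: list[Optional[str]] = []
        for part in lineage.split(";"):
            part = part.strip()
            if not part:
                break
            names.append(part)
        names += [None] * (len(RANKS) - len(names))
        return cls(tuple(names[: len(RANKS)]))

    def to_string(self) -> str:
        return ";".join(n for n in self.ranks if n is not None)

    @property
    def genus(self) -> Optional[str]:
        return self.ranks[RANKS.index("genus")]


@dataclass(frozen=True)
class ConsensusParams:
    """Voting parameters.

    top_n
        hits retained after sorting by descending bitscore (default 25).
    min_support
        exclusive support threshold; a name is assigned only if its
        weighted support strictly exceeds this (default 0.5 — strict
        majority, so at most one name can win a rank).
    weight_by_bitscore
        off ⇒ every retained hit counts 1 (for sensitivity analyses).
    """

    top_n: int = 25
    min_support: float = 0.5
    weight_by_bitscore: bool = True

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if not (0.5 <= self.min_support <= 1.0):
            raise ValueError("min_support must lie in [0.5, 1.0]")


@dataclass(frozen=True)
class CompositionTable:
    """Genus → percentage, summing to 100 (includes 'unclassified')."""

    entries: Mapping[str, float]

    def __post_init__(self) -> None:
        total = sum(self.entries.values())
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"composition sums to {total}, not 100")
        if any(v < 0 for v in self.entries.values()):
            raise ValueError("negative composition entry")

    def top(self, n: int = 10, min_count_filter: Optional[Mapping[str, float]] = None):
        return sorted(self.entries.items(), key=lambda kv: -kv[1])[:n]


def consensus_lineage(
    hits: Sequence[AlignmentRow], params: ConsensusParams = ConsensusParams()
) -> Lineage:
    """Rank-wise bitscore-weighted strict-majority vote over the top hits.

    Hits are sorted by descending bitscore (ties: subject accession
    ascending) and truncated to ``top_n``.  At each rank the support of a
    name is the weight of hits carrying it divided by the weight of *all*
    retained hits, so hits with unparseable/short lineages dilute support
    (conservative).  No hits ⇒ fully unassigned lineage.
    """
    if not hits:
        return Lineage.unassigned()
    queries = {h.query_accession for h in hits}
    if len(queries) > 1:
        raise ValueError(f"hits span multiple queries: {sorted(queries)}")
    retained = sorted(hits, key=lambda h: (-h.bitscore, h.subject_accession))[: params.top_n]
    weights = [h.bitscore if params.weight_by_bitscore else 1.0 for h in retained]
    total = sum(weights)
    parsed = [Lineage.from_string(h.subject_lineage) for h in retained]

    assigned: list[Optional[str]] = []
    for level in range(len(RANKS)):
        support: dict[str, float] = defaultdict(float)
        for lineage, weight in zip(parsed, weights):
            name = lineage.ranks[level]
            if name is not None:
                support[name] += weight
        winner = None
        for name, mass in sorted(support.items()):
            if mass / total > params.min_support:
                winner = name
                break
        if winner is None:
            break
        assigned.append(winner)
    assigned += [None] * (len(RANKS) - len(assigned))
    return Lineage(tuple(assigned))


def classify_all(
    alignments: Iterable[AlignmentRow], params: ConsensusParams = ConsensusParams()
) -> dict[str, Lineage]:
    """Consensus lineage for every query accession present in the input.

    Row order never matters; queries with no rows are absent.
    """
    by_query: dict[str, list[AlignmentRow]] = defaultdict(list)
    for row in alignments:
        by_query[row.query_accession].append(row)
    return {
        accession: consensus_lineage(rows, params)
        for accession, rows in sorted(by_query.items())
    }


def genus_composition(
    ids: Iterable[IdentificationRow],
    lineages: Mapping[str, Lineage],
    fraction_filter: Optional[str] = None,
) -> CompositionTable:
    """Spectral-count-weighted genus composition, normalized to 100%.

    Proteins without a lineage, or with an unassigned genus, fall into
    the explicit "unclassified" bucket.  Zero total spectral counts is
    an error — no composition is definable.
    """
    counts: dict[str, int] = defaultdict(int)
    total = 0
    for row in ids:
        if fraction_filter is not None and row.fraction != fraction_filter:
            continue
        lineage = lineages.get(row.protein_accession)
        genus = lineage.genus if lineage is not None else None
        counts[genus or UNCLASSIFIED] += row.spectral_count
        total += row.spectral_count
    if total == 0:
        raise ValueError("zero total spectral counts; composition undefined")
    # Integer counts + sorted iteration make the table independent of
    # input row order, down to the last float bit.
    entries = {genus: 100.0 * counts[genus] / total for genus in sorted(counts)}
    drift = 100.0 - sum(entries.values())
    if drift:
        top_genus = max(sorted(entries), key=lambda g: entries[g])
        entries[top_genus] += drift
    return CompositionTable(entries)


def write_lineage_tsv(lineages: Mapping[str, Lineage], path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("# accession\tlineage (superkingdom;...;species)\n")
        for accession in sorted(lineages):
            handle.write(f"{accession}\t{lineages[accession].to_string()}\n")


def write_composition_tsv(table: CompositionTable, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("genus\tpercent\n")
        for genus, pct in sorted(table.entries.items(), key=lambda kv: -kv[1]):
            handle.write(f"{genus}\t{pct:.4f}\n")
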