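"""Readers and writers for every external file the pipeline touches.

All downstream modules consume only the typed records defined here.
Dialects handled:

* protein FASTA — the accession is the header token before the first
  whitespace (PROKKA-style ids such as ``MMBJNONL_14124``).
* annotation table — InterProScan tab-separated layout, 11-15 columns,
  no header; columns 12/13 carry the integrated-entry id/description
  when present, ``-`` when absent.  Coordinates are 1-based inclusive.
* alignment table — 12-column BLAST/DIAMOND tabular
  (qseqid sseqid pident length mismatch gapopen qstart qend sstart send
  evalue bitscore) with one appended semicolon-delimited subject-lineage
  column, possibly empty.
* identification table — TSV (or CSV if the path ends in .csv) with a
  header: accession, fraction, sample_id, spectral_count, unique_peptides.
* candidate report — TSV or JSON, fixed column order (see
  :data:`REPORT_COLUMNS`).

Files are UTF-8 throughout.  Readers never silently drop rows: rows
rejected for a recoverable defect are counted in a :class:`ParseSummary`
and logged; unrecoverable defects (duplicate accessions, unknown
fraction labels, negative counts) are hard errors.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("ghmine.io")

AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
IPR_PATTERN = re.compile(r"^IPR\d{6}$")

PELLET = "pellet"
SUPERNATANT = "supernatant"
FRACTIONS = (PELLET, SUPERNATANT)

#: Fixed column order of the candidate report.
REPORT_COLUMNS = (
    "accession",
    "MW",
    "entry_ids",
    "entry_descs",
    "matched_keywords",
    "localization",
    "sup_spectral_count",
    "pellet_spectral_count",
    "rank",
)

#: Comment placed at the top of every emitted table.
DIALECT_HEADER = "# ghmine table; coordinates 1-based inclusive; UTF-8; tab-delimited"


class FormatError(ValueError):
    """Raised when an input file violates a hard invariant."""


@dataclass(frozen=True)
class ProteinEntry:
    """One translated ORF."""

    accession: str
    description: str = ""
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.accession:
            raise FormatError("protein accession must be non-empty")
        if self.sequence is not None:
            bad = set(self.sequence) - AMINO_ALPHABET
            if bad:
                raise FormatError(
                    f"{self.accession}: non-canonical residues {sorted(bad)}"
                )

    @property
    def length(self) -> Optional[int]:
        return None if self.sequence is None else len(self.sequence)


@dataclass(frozen=True)
class AnnotationRow:
    """One signature match on one ORF (the unit of the keyword screen)."""

    protein_accession: str
    source_db: str
    signature_id: str
    signature_desc: str
    start: int
    end: int
    entry_id: Optional[str] = None
    entry_desc: Optional[str] = None
    evalue: Optional[float] = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise FormatError(
                f"{self.protein_accession}: invalid span {self.start}..{self.end}"
            )
        if self.entry_id is not None and not IPR_PATTERN.match(self.entry_id):
            raise FormatError(f"malformed integrated entry id {self.entry_id!r}")
        if self.evalue is not None and self.evalue < 0:
            raise FormatError("evalue must be non-negative")


@dataclass(frozen=True)
class AlignmentRow:
    """One query-subject hit from a tabular aligner output."""

    query_accession: str
    subject_accession: str
    pct_identity: float
    align_length: int
    bitscore: float
    evalue: float
    subject_lineage: str = ""

    def __post_init__(self) -> None:
        if self.bitscore <= 0:
            raise FormatError("bitscore must be positive")
        if not (0.0 <= self.pct_identity <= 100.0):
            raise FormatError("percent identity outside [0, 100]")
        if self.align_length <= 0:
            raise FormatError("alignment length must be positive")
        if self.subject_lineage and len(self.subject_lineage.split(";")) > 7:
            raise FormatError("lineage has more than 7 ranks")


@dataclass(frozen=True)
class IdentificationRow:
    """One protein observation in one fraction of one sample."""

    protein_accession: str
    fraction: str
    sample_id: str
    spectral_count: int
    unique_peptides: int

    def __post_init__(self) -> None:
        if self.fraction not in FRACTIONS:
            raise FormatError(
                f"unknown fraction {self.fraction!r}; expected one of {FRACTIONS}"
            )
        if not (self.spectral_count >= self.unique_peptides >= 0):
            raise FormatError(
                f"{self.protein_accession}: require spectral_count >= "
                f"unique_peptides >= 0, got {self.spectral_count}/{self.unique_peptides}"
            )


@dataclass
class ParseSummary:
    """Bookkeeping for a reader run; rejected rows are never silent."""

    n_total: int = 0
    n_kept: int = 0
    n_rejected: int = 0
    warnings: list[str] = field(default_factory=list)

    def warn(self, message: str) -> None:
        self.warnings.append(message)
        logger.warning(message)


# ---------------------------------------------------------------------------
# FASTA


def read_protein_fasta(path: str | Path) -> list[ProteinEntry]:
    """Read a protein FASTA; accession = header token before first whitespace.

    Duplicate accessions are a hard error; an empty file yields an empty
    list with a warning.
    """
    path = Path(path)
    entries: list[ProteinEntry] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        accession = record.id
        if accession in seen:
            raise FormatError(f"duplicate accession {accession!r} in {path}")
        seen.add(accession)
        description = record.description[len(record.id):].strip()
        entries.append(
            ProteinEntry(accession, description, str(record.seq).upper() or None)
        )
    if not entries:
        logger.warning("no FASTA records in %s", path)
    return entries


def write_protein_fasta(entries: Iterable[ProteinEntry], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(e.sequence or ""), id=e.accession, description=e.description)
        for e in entries
    ]
    SeqIO.write(records, str(path), "fasta")


def split_fasta(path: str | Path, outdir: str | Path, chunk_size: int = 1000) -> list[Path]:
    """Split a FASTA into chunks of at most ``chunk_size`` proteins.

    Matches the batching convention of external annotators that choke on
    large inputs; returned paths are numbered in input order.
    """
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = read_protein_fasta(path)
    chunks: list[Path] = []
    for i in range(0, len(entries), chunk_size):
        chunk_path = outdir / f"{Path(path).stem}.chunk{i // chunk_size:04d}.faa"
        write_protein_fasta(entries[i : i + chunk_size], chunk_path)
        chunks.append(chunk_path)
    return chunks


# ---------------------------------------------------------------------------
# Annotation table (InterProScan dialect)

_MISSING = {"", "-"}


def read_annotation_tsv(path: str | Path) -> tuple[list[AnnotationRow], ParseSummary]:
    """Read an InterProScan-style TSV into annotation rows.

    Rows with start > end are rejected (warned, counted); a malformed
    integrated-entry id is downgraded to "entry absent" with a warning so
    the signature match itself is not lost.
    """
    path = Path(path)
    rows: list[AnnotationRow] = []
    summary = ParseSummary()
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            summary.n_total += 1
            cols = line.split("\t")
            if len(cols) < 8:
                summary.n_rejected += 1
                summary.warn(f"{path}:{lineno}: expected >=8 columns, got {len(cols)}")
                continue
            # Pad to the 15-column layout so optional columns index safely.
            cols += [""] * (15 - len(cols))
            try:
                start, end = int(cols[6]), int(cols[7])
            except ValueError:
                summary.n_rejected += 1
                summary.warn(f"{path}:{lineno}: non-integer coordinates")
                continue
            if start > end or start < 1:
                summary.n_rejected += 1
                summary.warn(f"{path}:{lineno}: invalid span {start}..{end}")
                continue
            entry_id = None if cols[11] in _MISSING else cols[11]
            entry_desc = None if cols[12] in _MISSING else cols[12]
            if entry_id is not None and not IPR_PATTERN.match(entry_id):
                summary.warn(
                    f"{path}:{lineno}: malformed entry id {entry_id!r}; kept without entry"
                )
                entry_id = None
                entry_desc = None
            try:
                evalue = None if cols[8] in _MISSING else float(cols[8])
            except ValueError:
                evalue = None
            rows.append(
                AnnotationRow(
                    protein_accession=cols[0],
                    source_db=cols[3],
                    signature_id=cols[4],
                    signature_desc=cols[5],
                    start=start,
                    end=end,
                    entry_id=entry_id,
                    entry_desc=entry_desc,
                    evalue=evalue,
                )
            )
            summary.n_kept += 1
    return rows, summary


def write_annotation_tsv(rows: Iterable[AnnotationRow], path: str | Path) -> None:
    """Write annotation rows in the 13-column InterProScan layout."""
    with open(path, "w", encoding="utf-8") as handle:
        for r in rows:
            evalue = "-" if r.evalue is None else format(r.evalue, "g")
            handle.write(
                "\t".join(
                    [
                        r.protein_accession,
                        "-",  # md5
                        "-",  # sequence length
                        r.source_db,
                        r.signature_id,
                        r.signature_desc,
                        str(r.start),
                        str(r.end),
                        evalue,
                        "T",
                        "-",  # date
                        r.entry_id or "-",
                        r.entry_desc or "-",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Alignment table (DIAMOND dialect + lineage column)


def read_alignment_tsv(path: str | Path) -> tuple[list[AlignmentRow], ParseSummary]:
    """Read 12-column tabular alignments with an optional 13th lineage column."""
    path = Path(path)
    rows: list[AlignmentRow] = []
    summary = ParseSummary()
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            summary.n_total += 1
            cols = line.split("\t")
            if len(cols) < 12:
                summary.n_rejected += 1
                summary.warn(f"{path}:{lineno}: expected >=12 columns, got {len(cols)}")
                continue
            lineage = cols[12] if len(cols) > 12 and cols[12] not in _MISSING else ""
            try:
                rows.append(
                    AlignmentRow(
                        query_accession=cols[0],
                        subject_accession=cols[1],
                        pct_identity=float(cols[2]),
                        align_length=int(cols[3]),
                        evalue=float(cols[10]),
                        bitscore=float(cols[11]),
                        subject_lineage=lineage,
                    )
                )
            except (ValueError, FormatError) as exc:
                summary.n_rejected += 1
                summary.warn(f"{path}:{lineno}: {exc}")
                continue
            summary.n_kept += 1
    return rows, summary


def write_alignment_tsv(rows: Iterable[AlignmentRow], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for r in rows:
            handle.write(
                "\t".join(
                    [
                        r.query_accession,
                        r.subject_accession,
                        format(r.pct_identity, "g"),
                        str(r.align_length),
                        "0",  # mismatch (not modeled)
                        "0",  # gapopen
                        "1",
                        str(r.align_length),
                        "1",
                        str(r.align_length),
                        format(r.evalue, "g"),
                        format(r.bitscore, "g"),
                        r.subject_lineage,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Identification tables


def read_identifications(path: str | Path) -> list[IdentificationRow]:
    """Read a fractionated identification table (TSV, or CSV for .csv paths).

    Unknown fraction labels and negative counts are hard errors — they
    indicate the wrong file, not a bad row.
    """
    path = Path(path)
    delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    rows: list[IdentificationRow] = []
    with open(path, encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(
            (line for line in handle if not line.startswith("#")),
            delimiter=delimiter,
        )
        required = {"accession", "fraction", "sample_id", "spectral_count", "unique_peptides"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise FormatError(
                f"{path}: identification table must have columns {sorted(required)}"
            )
        for record in reader:
            try:
                spectral = int(record["spectral_count"])
                unique = int(record["unique_peptides"])
            except ValueError as exc:
                raise FormatError(f"{path}: non-integer count: {exc}") from exc
            if spectral < 0 or unique < 0:
                raise FormatError(f"{path}: negative count for {record['accession']}")
            rows.append(
                IdentificationRow(
                    protein_accession=record["accession"],
                    fraction=record["fraction"],
                    sample_id=record["sample_id"],
                    spectral_count=spectral,
                    unique_peptides=unique,
                )
            )
    return rows


def write_identifications(rows: Iterable[IdentificationRow], path: str | Path) -> None:
    path = Path(path)
    delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter=delimiter, lineterminator="\n")
        writer.writerow(["accession", "fraction", "sample_id", "spectral_count", "unique_peptides"])
        for r in rows:
            writer.writerow(
                [r.protein_accession, r.fraction, r.sample_id, r.spectral_count, r.unique_peptides]
            )


# ---------------------------------------------------------------------------
# Candidate report


def _report_record(record) -> dict:
    """Flatten a candidate record (dataclass or mapping) to report columns."""
    get = record.get if isinstance(record, dict) else lambda k, d=None: getattr(record, k, d)
    mw = get("molecular_weight", get("MW"))
    return {
        "accession": get("protein_accession", get("accession")),
        "MW": "" if mw is None else str(int(round(float(mw)))),
        "entry_ids": ";".join(get("entry_ids") or ()),
        "entry_descs": ";".join(get("entry_descs") or ()),
        "matched_keywords": ";".join(get("matched_keywords") or ()),
        "localization": get("localization", ""),
        "sup_spectral_count": str(get("sup_count", get("sup_spectral_count", 0))),
        "pellet_spectral_count": str(get("pellet_count", get("pellet_spectral_count", 0))),
        "rank": str(get("rank", "")),
    }


def write_candidate_report(records: Sequence, path: str | Path, format: str = "tsv") -> None:
    """Write the candidate report with a deterministic column order.

    ``format`` is ``"tsv"`` (commented dialect header + header row) or
    ``"json"`` (array of flat objects).
    """
    path = Path(path)
    flats = [_report_record(r) for r in records]
    if format == "tsv":
        with open(path, "w", encoding="utf-8") as handle:
            handle.write(DIALECT_HEADER + "\n")
            handle.write("\t".join(REPORT_COLUMNS) + "\n")
            for flat in flats:
                handle.write("\t".join(flat[c] for c in REPORT_COLUMNS) + "\n")
    elif format == "json":
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(flats, handle, indent=1)
            handle.write("\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_candidate_report(path: str | Path) -> list[dict]:
    """Read back a TSV or JSON candidate report as a list of flat dicts."""
    path = Path(path)
    if path.suffix == ".json":
        with open(path, encoding="utf-8") as handle:
            return json.load(handle)
    records: list[dict] = []
    with open(path, encoding="utf-8") as handle:
        lines = [ln.rstrip("\n") for ln in handle if not ln.startswith("#")]
    if not lines:
        return records
    header = lines[0].split("\t")
    for line in lines[1:]:
        if line:
            records.append(dict(zip(header, line.split("\t"))))
    return records
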