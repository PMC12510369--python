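"""End-to-end discovery pipeline: all genes → keyword-flagged → expressed
→ localized → ranked candidates, with taxonomy and lysis QC on the side.

The funnel mirrors how enrichment-metaproteomics narrows a metagenome:
thousands of ORFs, a keyword-flagged subset (plus retained unannotated
genes), the expressed subset seen by proteomics, and finally small
intracellular and extracellular candidate lists ranked by abundance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import annotation_screen, io_formats, proteomics, synthetic_data, taxonomy
from .io_formats import PELLET, SUPERNATANT

logger = logging.getLogger("ghmine.pipeline")


class PipelineError(RuntimeError):
    """A hard error in a named pipeline stage."""


@dataclass
class PipelineConfig:
    """Declarative run configuration; CLI flags override file values."""

    fasta: Optional[str] = None
    annotations: Optional[str] = None
    alignments: Optional[str] = None
    identifications: Sequence[str] = ()
    keywords: Sequence[str] = annotation_screen.DEFAULT_KEYWORDS
    top_n: int = 25
    min_support: float = 0.5
    weight_by_bitscore: bool = True
    min_unique_peptides: int = 2
    top_k: int = 50
    markers: Sequence[str] = proteomics.DEFAULT_MARKERS
    chunk_size: int = 1000
    outdir: str = "ghmine_run"
    seed: int = 0
    simulate: Optional[dict] = None  # scenario/n_orfs/lysis_rate block
    molecular_weights: Optional[dict] = None  # accession -> Da, for sequence-free inputs

    def __post_init__(self) -> None:
        if self.chunk_size < 1:
            raise ValueError("chunk_size must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False), encoding="utf-8"
        )


@dataclass
class FunnelSummary:
    """Stage-by-stage counts of the discovery funnel."""

    total_genes: int = 0
    keyword_flagged: int = 0
    expressed: int = 0
    intracellular_candidates: int = 0
    extracellular_candidates: int = 0
    notes: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage(name: str):
    def decorator(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name}: {exc}") from exc

        return wrapped

    return decorator


def run_discovery(config: PipelineConfig) -> FunnelSummary:
    """Execute io → taxonomy → keyword screen → proteomics integration.

    Writes lineages, composition, candidate flags, both ranked candidate
    reports (TSV + JSON), the lysis-QC JSON and a funnel manifest under
    ``config.outdir``.  Recoverable conditions (no identifications, no
    pellet, zero spectral counts) are recorded in the summary notes, not
    raised.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary = FunnelSummary()

    if config.simulate is not None:
        sim = dict(config.simulate)
        sim.setdefault("seed", config.seed)
        manifest = _stage("simulate")(synthetic_data.generate_dataset)(
            outdir / "data", **sim
        )
        config = dataclasses.replace(
            config,
            fasta=manifest["files"]["proteins"],
            annotations=manifest["files"]["annotations"],
            alignments=manifest["files"]["alignments"],
            identifications=[manifest["files"]["identifications"]],
        )

    # --- io -----------------------------------------------------------------
    @_stage("io")
    def load():
        if config.fasta is None or config.annotations is None:
            raise ValueError("config must provide fasta and annotations paths")
        proteins = io_formats.read_protein_fasta(config.fasta)
        annotations, ann_summary = io_formats.read_annotation_tsv(config.annotations)
        if ann_summary.n_rejected:
            summary.notes.append(
                f"{ann_summary.n_rejected} annotation rows rejected"
            )
        alignments = []
        if config.alignments:
            alignments, _ = io_formats.read_alignment_tsv(config.alignments)
        ids = []
        for path in config.identifications:
            ids.extend(io_formats.read_identifications(path))
        return proteins, annotations, alignments, ids

    proteins, annotations, alignments, ids = load()
    summary.total_genes = len(proteins)

    # --- taxonomy -----------------------------------------------------------
    params = taxonomy.ConsensusParams(
        top_n=config.top_n,
        min_support=config.min_support,
        weight_by_bitscore=config.weight_by_bitscore,
    )
    lineages = _stage("taxonomy")(taxonomy.classify_all)(alignments, params)
    taxonomy.write_lineage_tsv(lineages, outdir / "lineages.tsv")

    # --- keyword screen -----------------------------------------------------
    flags = _stage("annotation_screen")(annotation_screen.screen)(
        annotations,
        proteins,
        annotation_screen.KeywordSet(tuple(config.keywords)),
    )
    annotation_screen.write_flags_tsv(flags, outdir / "candidate_flags.tsv")
    summary.keyword_flagged = sum(1 for f in flags if f.is_candidate)

    # --- proteomics integration --------------------------------------------
    filtered = proteomics.apply_id_criteria(ids, config.min_unique_peptides)
    calls = _stage("proteomics_integration")(proteomics.classify_localization)(filtered)
    summary.expressed = len(calls)

    descriptions = {p.accession: p.description for p in proteins}
    mw = dict(config.molecular_weights or {})
    for p in proteins:
        if p.accession not in mw and p.sequence:
            try:
                mw[p.accession] = proteomics.compute_molecular_weight(p.sequence)
            except ValueError:
                pass  # non-canonical residues: leave MW blank
    entries: dict[str, list[tuple[str, str]]] = {}
    for row in annotations:
        if row.entry_id is not None:
            entries.setdefault(row.protein_accession, []).append(
                (row.entry_id, row.entry_desc or "")
            )

    reports = {}
    for fraction, label in ((SUPERNATANT, "extracellular"), (PELLET, "intracellular")):
        records = _stage("proteomics_integration")(proteomics.rank_candidates)(
            flags, calls, fraction, molecular_weights=mw, entries=entries
        )
        reports[label] = records
        io_formats.write_candidate_report(
            records, outdir / f"candidates_{label}.tsv", "tsv"
        )
        io_formats.write_candidate_report(
            records, outdir / f"candidates_{label}.json", "json"
        )
    summary.extracellular_candidates = len(reports["extracellular"])
    summary.intracellular_candidates = len(reports["intracellular"])

    # --- lysis QC -----------------------------------------------------------
    try:
        qc = proteomics.lysis_qc(
            filtered, descriptions, top_k=config.top_k, markers=tuple(config.markers)
        )
        qc_payload = {
            "top_k": qc.top_k,
            "absent_from_secretome": qc.absent_from_secretome,
            "marker_hits": dict(qc.marker_hits),
        }
    except ValueError as exc:
        summary.notes.append(f"lysis QC skipped: {exc}")
        qc_payload = {"error": str(exc)}
    (outdir / "qc.json").write_text(
        json.dumps(qc_payload, indent=1) + "\n", encoding="utf-8"
    )

    # --- composition --------------------------------------------------------
    try:
        composition = taxonomy.genus_composition(filtered, lineages)
        taxonomy.write_composition_tsv(composition, outdir / "composition.tsv")
    except ValueError as exc:
        summary.notes.append(f"composition skipped: {exc}")

    (outdir / "funnel.json").write_text(
        json.dumps(summary.as_dict(), indent=1) + "\n", encoding="utf-8"
    )
    logger.info(
        "funnel: %d genes -> %d flagged -> %d expressed -> %d intracellular + %d extracellular",
        summary.total_genes,
        summary.keyword_flagged,
        summary.expressed,
        summary.intracellular_candidates,
        summary.extracellular_candidates,
    )
    return summary
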