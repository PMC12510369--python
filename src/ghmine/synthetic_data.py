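"""Ground-truth-labeled synthetic inputs for the discovery pipeline.

The raw sequencing and mass-spectrometry data behind this kind of study
are rarely shareable, so every pipeline stage is exercised on generated
inputs with known truth.  Two scenarios are modeled:

* an *inoculum*-like community — high diversity (>100 genera), most ORFs
  carrying alignments with no informative lineage, so the consensus
  classifier leaves them unassigned;
* an *enrichment*-like community — one dominant genus (default
  ``Alicyclobacillus`` at 70% of spectral counts) plus a low-abundance
  tail.

Each ORF receives a genus, a functional role (secreted glycoside
hydrolase, intracellular GH, glycolytic marker, maltodextrin
transporter, or housekeeping), a random protein sequence, annotation
rows drawn from a GH13-flavoured InterPro vocabulary (suppressed at a
configurable missing rate), and up to 25 alignment rows with descending
bitscores.  One secreted-GH ORF is *planted* as an amylopullulanase-like
enzyme whose supernatant abundance dwarfs all other secreted proteins —
the generator's statement that an enzyme essential for growth on the
sole carbon source must be highly expressed.

Spectral counts are negative-binomial (overdispersed) with
role-by-fraction means; intracellular roles reach the supernatant only
through a tunable ``lysis_rate`` (supernatant mean = lysis_rate × pellet
mean), which is the knob for cytoplasmic-contamination QC experiments.
Identical seeds give byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np

from .io_formats import (
    PELLET,
    SUPERNATANT,
    AlignmentRow,
    AnnotationRow,
    IdentificationRow,
    ProteinEntry,
    write_alignment_tsv,
    write_annotation_tsv,
    write_identifications,
    write_protein_fasta,
)

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

SECRETED_GH = "secreted-GH"
INTRACELLULAR_GH = "intracellular-GH"
GLYCOLYTIC_MARKER = "glycolytic-marker"
TRANSPORTER = "transporter"
HOUSEKEEPING = "housekeeping"
ROLES = (SECRETED_GH, INTRACELLULAR_GH, GLYCOLYTIC_MARKER, TRANSPORTER, HOUSEKEEPING)

MARKER_DESCRIPTIONS = (
    "Glyceraldehyde-3-phosphate dehydrogenase",
    "Phosphoglycerate mutase",
    "Glucose-6-phosphate isomerase",
)
TRANSPORTER_DESCRIPTIONS = (
    "Maltose/maltodextrin transport system permease MalG",
    "Maltose/maltodextrin-binding periplasmic protein",
)
HOUSEKEEPING_DESCRIPTIONS = (
    "Ribosomal protein L2",
    "DNA-directed RNA polymerase subunit beta",
    "Chaperone protein DnaK",
    "Elongation factor Tu",
    "ATP synthase subunit alpha",
)

#: InterPro vocabulary used for GH-role annotation rows.
IPR_DESCRIPTIONS: dict[str, str] = {
    "IPR006047": "Glycoside hydrolase, family 13, catalytic domain",
    "IPR004185": "Glycoside hydrolase, family 13, N-terminal Ig-like domain",
    "IPR017853": "Glycoside hydrolase superfamily",
    "IPR015020": "Rv2525c-like, glycoside hydrolase-like domain",
    "IPR015955": "Lactate dehydrogenase/glycoside hydrolase, family 4, C-terminal",
}
_GH_ENTRY_CHOICES = ("IPR006047", "IPR017853", "IPR015020", "IPR015955")

_GENUS_PREFIXES = (
    "Alicyclo", "Thermo", "Acido", "Geo", "Methano", "Caldi", "Sulfo",
    "Paeni", "Rhodo", "Chloro", "Desulfo", "Halo", "Nitro", "Pyro",
)
_GENUS_STEMS = (
    "bacillus", "coccus", "monas", "bacter", "spira", "filum", "culleus",
    "sarcina", "thrix", "vibrio",
)


def genus_pool(n: int) -> list[str]:
    """Deterministic pool of ≥n distinct plausible genus names."""
    names = [p + s for p in _GENUS_PREFIXES for s in _GENUS_STEMS]
    if n > len(names):
        names += [f"Candidatus-genus-{i}" for i in range(n - len(names))]
    return names[:n]


def lineage_for_genus(genus: str) -> str:
    """Seven-rank lineage string shared by all members of a genus."""
    if genus == "Alicyclobacillus":
        return (
            "Bacteria;Bacillota;Bacilli;Bacillales;Alicyclobacillaceae;"
            "Alicyclobacillus;Alicyclobacillus sp."
        )
    return (
        f"Bacteria;{genus}-phylum;{genus}-class;{genus}-order;"
        f"{genus}-family;{genus};{genus} sp."
    )


@dataclass(frozen=True)
class CommunitySpec:
    """Genus mixture and classifiability of a simulated community."""

    genus_weights: Mapping[str, float]
    n_orfs: int = 2000
    unclassifiable_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.genus_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"genus weights sum to {total}, not 1")
        if not (0.0 <= self.unclassifiable_fraction <= 1.0):
            raise ValueError("unclassifiable_fraction outside [0, 1]")
        if self.n_orfs < 1:
            raise ValueError("n_orfs must be >= 1")


def enrichment_community(
    dominant: str = "Alicyclobacillus",
    dominant_weight: float = 0.7,
    n_other: int = 12,
    n_orfs: int = 2000,
    unclassifiable_fraction: float = 0.05,
    seed: int = 0,
) -> CommunitySpec:
    """One genus dominating over a low-abundance tail.

    ``dominant_weight`` is the target *observable* share of spectral
    counts assigned to the dominant genus (the number a composition
    table reports).  Because unclassifiable ORFs divert their counts to
    the "unclassified" bucket, the underlying genus weight is inflated
    by 1/(1 − unclassifiable_fraction) so the classified share lands on
    the target.
    """
    others = [g for g in genus_pool(n_other + 1) if g != dominant][:n_other]
    adjusted = min(1.0, dominant_weight / (1.0 - unclassifiable_fraction))
    tail = (1.0 - adjusted) / n_other
    weights = {dominant: adjusted, **{g: tail for g in others}}
    return CommunitySpec(weights, n_orfs, unclassifiable_fraction, seed)


def inoculum_community(
    n_genera: int = 120,
    n_orfs: int = 2000,
    unclassifiable_fraction: float = 0.8,
    seed: int = 0,
) -> CommunitySpec:
    """High-diversity community: >100 genera with geometric-tail weights.

    The 0.98 decay keeps even the rarest of the 120 genera likely to be
    drawn at desk scale (2000 ORFs), so the >100-genus condition holds.
    """
    names = genus_pool(n_genera)
    raw = np.power(0.98, np.arange(n_genera))
    weights = dict(zip(names, (raw / raw.sum()).tolist()))
    # normalize residual float drift onto the first genus
    weights[names[0]] += 1.0 - sum(weights.values())
    return CommunitySpec(weights, n_orfs, unclassifiable_fraction, seed)


@dataclass(frozen=True)
class ExpressionSpec:
    """Role/fraction count model for the simulated metaproteome.

    Intracellular roles get supernatant mean = ``lysis_rate`` × pellet
    mean; the planted secreted GH gets ``planted_sup_mean``.  Counts are
    negative-binomial with shape ``dispersion``; rows whose count falls
    below ``min_detect`` are not emitted.
    """

    role_expression_prob: Mapping[str, float] = field(
        default_factory=lambda: {
            SECRETED_GH: 1.0,
            INTRACELLULAR_GH: 0.9,
            GLYCOLYTIC_MARKER: 1.0,
            TRANSPORTER: 0.8,
            HOUSEKEEPING: 0.15,
        }
    )
    pellet_means: Mapping[str, float] = field(
        default_factory=lambda: {
            SECRETED_GH: 15.0,
            INTRACELLULAR_GH: 40.0,
            GLYCOLYTIC_MARKER: 80.0,
            TRANSPORTER: 25.0,
            HOUSEKEEPING: 12.0,
        }
    )
    sup_means: Mapping[str, float] = field(default_factory=lambda: {SECRETED_GH: 40.0})
    planted_sup_mean: float = 400.0
    dispersion: float = 8.0
    lysis_rate: float = 0.02
    min_detect: int = 1
    n_samples: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.lysis_rate <= 1.0):
            raise ValueError("lysis_rate outside [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if any(m < 0 for m in self.pellet_means.values()):
            raise ValueError("negative pellet mean")


@dataclass(frozen=True)
class OrfTruth:
    accession: str
    genus: str
    role: str
    localization: str  # secreted | intracellular
    annotated: bool
    description: str
    unclassifiable: bool


@dataclass
class GroundTruth:
    orfs: dict[str, OrfTruth]
    planted_top_secreted: str

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_top_secreted": self.planted_top_secreted,
            "orfs": {acc: asdict(t) for acc, t in sorted(self.orfs.items())},
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")


@dataclass
class Metagenome:
    proteins: list[ProteinEntry]
    annotations: list[AnnotationRow]
    alignments: list[AlignmentRow]
    truth: GroundTruth


def _draw_roles(rng: np.random.Generator, n: int, gh_fraction: float) -> list[str]:
    probs = {
        SECRETED_GH: gh_fraction * 0.2,
        INTRACELLULAR_GH: gh_fraction * 0.8,
        GLYCOLYTIC_MARKER: 0.03,
        TRANSPORTER: 0.03,
    }
    probs[HOUSEKEEPING] = 1.0 - sum(probs.values())
    roles = list(rng.choice(ROLES, size=n, p=[probs[r] for r in ROLES]))
    if gh_fraction > 0 and SECRETED_GH not in roles:
        roles[0] = SECRETED_GH  # the scenario requires a planted secreted GH
    return [str(r) for r in roles]


def _description_for(role: str, index: int, planted: bool) -> str:
    if planted:
        return "Amylopullulanase, extracellular pullulan-degrading enzyme"
    if role in (SECRETED_GH, INTRACELLULAR_GH):
        return "Glycoside hydrolase family protein"
    if role == GLYCOLYTIC_MARKER:
        return MARKER_DESCRIPTIONS[index % len(MARKER_DESCRIPTIONS)]
    if role == TRANSPORTER:
        return TRANSPORTER_DESCRIPTIONS[index % len(TRANSPORTER_DESCRIPTIONS)]
    return HOUSEKEEPING_DESCRIPTIONS[index % len(HOUSEKEEPING_DESCRIPTIONS)]


def generate_metagenome(
    community: CommunitySpec,
    gh_fraction: float = 0.07,
    annotation_missing_rate: float = 0.3,
    contamination_rate: float = 0.02,
) -> Metagenome:
    """Simulate ORFs, annotations and alignment hits for a community.

    GH-role ORFs receive GH13-flavoured annotation rows unless suppressed
    at ``annotation_missing_rate`` (which also silences other roles);
    every ORF gets 5-25 alignment rows with descending bitscores whose
    lineages equal the true lineage, contaminated at ``contamination_rate``
    with a random other genus.  Unclassifiable ORFs get lineage-free hits.
    """
    if not (0.0 <= gh_fraction <= 1.0):
        raise ValueError("gh_fraction outside [0, 1]")
    if not (0.0 <= annotation_missing_rate <= 1.0):
        raise ValueError("annotation_missing_rate outside [0, 1]")
    # Distinct stream index per generator so equal seeds never correlate
    # the genus draw with the later expression draw.
    rng = np.random.default_rng([0, community.seed])
    genera = sorted(community.genus_weights)
    weights = np.array([community.genus_weights[g] for g in genera])
    weights = weights / weights.sum()

    n = community.n_orfs
    orf_genera = [genera[i] for i in rng.choice(len(genera), size=n, p=weights)]
    roles = _draw_roles(rng, n, gh_fraction)
    planted = next(i for i, r in enumerate(roles) if r == SECRETED_GH) if gh_fraction > 0 else -1
    if planted >= 0:
        # The planted amylopullulanase belongs to the highest-weight genus:
        # the organism enriched on the sole carbon source is the one that
        # must express its extracellular hydrolase.
        dominant = max(community.genus_weights, key=community.genus_weights.__getitem__)
        orf_genera[planted] = dominant
    unclassifiable = rng.random(n) < community.unclassifiable_fraction
    missing = rng.random(n) < annotation_missing_rate

    proteins: list[ProteinEntry] = []
    annotations: list[AnnotationRow] = []
    alignments: list[AlignmentRow] = []
    orfs: dict[str, OrfTruth] = {}

    for i in range(n):
        accession = f"ORF_{i:05d}"
        role = roles[i]
        is_planted = i == planted
        length = int(rng.integers(1200 if is_planted else 120, 1300 if is_planted else 600))
        sequence = "".join(AMINO_ACIDS[rng.integers(0, 20, size=length)])
        description = _description_for(role, i, is_planted)
        proteins.append(ProteinEntry(accession, description, sequence))

        annotated = is_planted or not missing[i]
        if annotated:
            if role in (SECRETED_GH, INTRACELLULAR_GH):
                if is_planted:
                    entry_ids = ["IPR006047", "IPR004185", "IPR017853"]
                else:
                    k = int(rng.integers(1, 3))
                    entry_ids = list(
                        rng.choice(_GH_ENTRY_CHOICES, size=k, replace=False)
                    )
                for entry_id in entry_ids:
                    end = int(rng.integers(80, max(81, length)))
                    annotations.append(
                        AnnotationRow(
                            protein_accession=accession,
                            source_db="SyntheticHMM",
                            signature_id=f"SIG{entry_id[3:]}",
                            signature_desc=IPR_DESCRIPTIONS[entry_id],
                            start=1,
                            end=end,
                            entry_id=entry_id,
                            entry_desc=IPR_DESCRIPTIONS[entry_id],
                            evalue=float(f"{rng.uniform(1e-60, 1e-10):.3g}"),
                        )
                    )
            else:
                annotations.append(
                    AnnotationRow(
                        protein_accession=accession,
                        source_db="SyntheticHMM",
                        signature_id=f"HK{i % 97:04d}",
                        signature_desc=description,
                        start=1,
                        end=length,
                        entry_id=None,
                        entry_desc=None,
                        evalue=float(f"{rng.uniform(1e-40, 1e-5):.3g}"),
                    )
                )

        n_hits = int(rng.integers(5, 26))
        top_score = float(rng.uniform(300.0, 900.0))
        for h in range(n_hits):
            bitscore = round(top_score * float(np.exp(-0.08 * h)), 1)
            if unclassifiable[i]:
                lineage = ""
            elif rng.random() < contamination_rate:
                other = genera[int(rng.integers(0, len(genera)))]
                lineage = lineage_for_genus(other)
            else:
                lineage = lineage_for_genus(orf_genera[i])
            alignments.append(
                AlignmentRow(
                    query_accession=accession,
                    subject_accession=f"REF_{i:05d}_{h:02d}",
                    pct_identity=round(float(rng.uniform(35.0, 99.0)), 1),
                    align_length=max(30, int(length * rng.uniform(0.5, 1.0))),
                    bitscore=max(bitscore, 1.0),
                    evalue=float(f"{rng.uniform(1e-80, 1e-10):.3g}"),
                    subject_lineage=lineage,
                )
            )

        orfs[accession] = OrfTruth(
            accession=accession,
            genus=orf_genera[i],
            role=role,
            localization="secreted" if role == SECRETED_GH else "intracellular",
            annotated=annotated,
            description=description,
            unclassifiable=bool(unclassifiable[i]),
        )

    truth = GroundTruth(
        orfs=orfs,
        planted_top_secreted=f"ORF_{planted:05d}" if planted >= 0 else "",
    )
    return Metagenome(proteins, annotations, alignments, truth)


def generate_identifications(
    truth: GroundTruth,
    expr: ExpressionSpec = ExpressionSpec(),
    depth: Optional[int] = None,
) -> list[IdentificationRow]:
    """Draw fractionated spectral-count tables consistent with the truth.

    ``depth`` rescales all means so the expected grand-total spectral
    count matches it (used to study composition-estimate convergence).
    """
    rng = np.random.default_rng([1, expr.seed])
    orfs = [truth.orfs[a] for a in sorted(truth.orfs)]
    expressed = {
        o.accession: rng.random() < expr.role_expression_prob.get(o.role, 0.0)
        for o in orfs
    }

    def mean_for(orf: OrfTruth, fraction: str) -> float:
        pellet_mean = expr.pellet_means.get(orf.role, 0.0)
        if fraction == PELLET:
            return pellet_mean
        if orf.accession == truth.planted_top_secreted:
            return expr.planted_sup_mean
        if orf.role in expr.sup_means:
            return expr.sup_means[orf.role]
        return expr.lysis_rate * pellet_mean

    scale = 1.0
    if depth is not None:
        expected = sum(
            mean_for(o, fr) * expr.n_samples
            for o in orfs
            if expressed[o.accession]
            for fr in (PELLET, SUPERNATANT)
        )
        if expected > 0:
            scale = depth / expected

    rows: list[IdentificationRow] = []
    shape = expr.dispersion
    for orf in orfs:
        if not expressed[orf.accession]:
            continue
        for fraction in (PELLET, SUPERNATANT):
            mean = mean_for(orf, fraction) * scale
            for s in range(expr.n_samples):
                if mean <= 0:
                    continue
                p = shape / (shape + mean)
                count = int(rng.negative_binomial(shape, p))
                if count < expr.min_detect:
                    continue
                unique = int(min(count, 1 + rng.poisson(1.0 + count / 20.0)))
                rows.append(
                    IdentificationRow(
                        protein_accession=orf.accession,
                        fraction=fraction,
                        sample_id=f"{'P' if fraction == PELLET else 'SN'}{s + 1}",
                        spectral_count=count,
                        unique_peptides=unique,
                    )
                )
    return rows


def generate_dataset(
    outdir: str | Path,
    scenario: str = "enrichment",
    n_orfs: int = 2000,
    seed: int = 0,
    lysis_rate: float = 0.02,
    paper_scale: bool = False,
) -> dict:
    """Write a complete input set (FASTA + three tables + truth + manifest).

    Identical arguments give byte-identical files.  Returns the manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if paper_scale:
        n_orfs = 14000
    if scenario == "enrichment":
        community = enrichment_community(n_orfs=n_orfs, seed=seed)
    elif scenario == "inoculum":
        community = inoculum_community(n_orfs=n_orfs, seed=seed)
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    metagenome = generate_metagenome(community)
    expr = ExpressionSpec(lysis_rate=lysis_rate, seed=seed)
    ids = generate_identifications(metagenome.truth, expr)

    paths = {
        "proteins": outdir / "proteins.faa",
        "annotations": outdir / "annotations.tsv",
        "alignments": outdir / "alignments.tsv",
        "identifications": outdir / "identifications.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_protein_fasta(metagenome.proteins, paths["proteins"])
    write_annotation_tsv(metagenome.annotations, paths["annotations"])
    write_alignment_tsv(metagenome.alignments, paths["alignments"])
    write_identifications(ids, paths["identifications"])
    metagenome.truth.to_json(paths["ground_truth"])

    manifest = {
        "scenario": scenario,
        "n_orfs": n_orfs,
        "seed": seed,
        "lysis_rate": lysis_rate,
        "planted_top_secreted": metagenome.truth.planted_top_secreted,
        "files": {k: str(v) for k, v in paths.items()},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1) + "\n", encoding="utf-8"
    )
    return manifest


# ---------------------------------------------------------------------------
# Worked-example fixture: the 17 secretome candidates of the source study.

#: (accession, MW in Da, integrated entry ids) — the printed report rows.
SECRETOME_TABLE_ROWS: tuple[tuple[str, int, tuple[str, ...]], ...] = (
    ("MMBJNONL_14124", 140550, ("IPR006047", "IPR004185", "IPR017853")),
    ("MMBJNONL_07072", 91271, ("IPR006047", "IPR004185", "IPR017853")),
    ("MMBJNONL_03000", 75891, ("IPR015020", "IPR017853")),
    ("MMBJNONL_05960", 58192, ("IPR017853",)),
    ("MMBJNONL_09916", 33232, ("IPR015955",)),
    ("MMBJNONL_07048", 33418, ("IPR015955",)),
    ("MMBJNONL_05225", 21160, ()),
    ("MMBJNONL_03006", 18307, ()),
    ("MMBJNONL_05223", 27924, ()),
    ("MMBJNONL_09075", 32173, ()),
    ("MMBJNONL_01486", 47258, ()),
    ("MMBJNONL_05876", 18086, ()),
    ("MMBJNONL_03029", 18064, ()),
    ("MMBJNONL_02580", 15965, ()),
    ("MMBJNONL_02999", 13289, ()),
    ("MMBJNONL_07823", 21122, ()),
    ("MMBJNONL_01632", 28355, ()),
)


@dataclass
class SecretomeFixture:
    proteins: list[ProteinEntry]
    annotations: list[AnnotationRow]
    identifications: list[IdentificationRow]
    molecular_weights: dict[str, float]

    @property
    def accessions(self) -> list[str]:
        return [p.accession for p in self.proteins]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "proteins": outdir / "secretome_proteins.faa",
            "annotations": outdir / "secretome_annotations.tsv",
            "identifications": outdir / "secretome_identifications.tsv",
        }
        write_protein_fasta(self.proteins, paths["proteins"])
        write_annotation_tsv(self.annotations, paths["annotations"])
        write_identifications(self.identifications, paths["identifications"])
        return paths


def secretome_fixture() -> SecretomeFixture:
    """The published 17-protein secretome candidate list as pipeline input.

    Accessions, molecular weights and InterPro entries are as printed;
    spectral counts were published only as bar heights, so the fixture
    assigns arbitrary descending placeholder counts (non-authoritative —
    use presence/absence and annotation content only).  Sequences are not
    public, so protein entries carry no sequence.
    """
    proteins: list[ProteinEntry] = []
    annotations: list[AnnotationRow] = []
    identifications: list[IdentificationRow] = []
    weights: dict[str, float] = {}
    for i, (accession, mw, entry_ids) in enumerate(SECRETOME_TABLE_ROWS):
        proteins.append(
            ProteinEntry(
                accession,
                "secretome candidate (published worked example)",
                None,
            )
        )
        weights[accession] = float(mw)
        approx_len = max(50, mw // 110)
        for entry_id in entry_ids:
            annotations.append(
                AnnotationRow(
                    protein_accession=accession,
                    source_db="InterProScan",
                    signature_id=f"SIG{entry_id[3:]}",
                    signature_desc=IPR_DESCRIPTIONS[entry_id],
                    start=1,
                    end=int(approx_len),
                    entry_id=entry_id,
                    entry_desc=IPR_DESCRIPTIONS[entry_id],
                )
            )
        identifications.append(
            IdentificationRow(
                protein_accession=accession,
                fraction=SUPERNATANT,
                sample_id="SN1",
                spectral_count=60 - 3 * i,  # placeholder, non-authoritative
                unique_peptides=min(60 - 3 * i, 3),
            )
        )
    return SecretomeFixture(proteins, annotations, identifications, weights)
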