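# Methods

## Input formats and conventions

All inputs are plain text, UTF-8, tab-delimited. Annotation coordinates
are 1-based inclusive. Protein accessions are the FASTA header token
before the first whitespace. Annotation tables follow the InterProScan
tabular layout (11–15 columns; columns 12/13 carry the integrated entry
id/description, `-` when absent); a missing integrated entry is
represented as *absent*, never as an empty string, so "unannotated" is
unambiguous. Alignment tables are 12-column BLAST/DIAMOND tabular with
one appended semicolon-delimited subject lineage (superkingdom →
species, possibly truncated). Readers never drop rows silently:
recoverable defects (inverted spans, malformed entry ids) are counted
in a parse summary and logged; duplicate accessions, unknown fraction
labels and negative counts are hard errors because they indicate the
wrong file rather than a bad row.

## Consensus taxonomy

For one query, hits are sorted by descending bitscore (ties broken by
subject accession so results are deterministic) and truncated to the
top `top_n` (default 25). At each rank from superkingdom downward, a
name's support is the summed bitscore of hits carrying it divided by
the summed bitscore of *all* retained hits; the name is assigned iff
its support strictly exceeds `min_support` (default 0.5 — strict
majority, so at most one name can win). The first rank without a
winner ends the lineage, and hits with unparseable or truncated
lineages dilute support rather than being excluded (conservative:
conflicting or uninformative evidence degrades the assignment). With
`weight_by_bitscore` off, each retained hit counts 1; this is exposed
for sensitivity analyses only. Whether the original consensus scheme
used strict majority, plurality, or another threshold is not something
the pipeline can know; the threshold is therefore a parameter, and the
strict-majority default is what the equivalence tests pin down.

Community composition is spectral-count weighted: per-genus summed
counts over the grand total, normalized to 100%, with an explicit
`unclassified` bucket. Normalization is over *all* proteins; any
display filtering (e.g. genera above a count threshold) is left to
report time. Integer accumulation plus sorted iteration makes the
table bit-identical under input permutation.

## Keyword screen

Matching is case-insensitive plain substring after Unicode NFC
normalization, applied to signature id, signature description,
integrated entry id and entry description of every row for a protein.
No word boundaries are used on purpose: subfamily-style signature ids
such as `GH13_39` must hit the `GH13` keyword. The default list is
frozen to the eight strings in the README. "Unannotated" means zero
annotation rows; a stricter mode (no integrated entry) exists behind a
flag, default off, because a signature-only match is still an
annotation. Candidacy is monotone in the keyword set — enlarging it
can only add candidates — and this is property-tested.

## Proteomics integration

The identification criterion is ≥2 unique peptides per protein; FDR
control is assumed applied by the upstream search engine and is not
recomputed. Abundance is the summed spectral count across samples per
fraction (no NSAF/length normalization by default; it can be layered
on by callers). A protein passing the criterion in at least one
supernatant sample is called **secreted** even when also found in the
pellet — secreted enzymes are frequently cell-associated — and a
`both` sub-label is retained for QC; pellet-only proteins are
**intracellular**. The two calls partition the identified set. Whether
the intracellular class of the original analysis excluded
supernatant-detected proteins is one consistent reading among several;
this partition is a design decision, not a restated fact.

Ranking sorts the candidate ∩ localization-class set by descending
count in the class-defining fraction, ties by accession, ranks 1..n.
Molecular weight is the average (not monoisotopic) mass: sum of free
amino-acid average masses minus one water per peptide bond, empty
chain = one water (18.0153 Da); `X` has no defined average mass and is
an error, and the pipeline simply leaves MW blank for such sequences.

The lysis QC takes the `top_k` (default 50) pellet proteins by count
(ties by accession), counts how many never appear in the supernatant,
and sums supernatant counts of proteins whose description contains one
of the glycolytic marker names (case-insensitive substring). Marker
matching by description suits the synthetic data, where roles are
labeled explicitly; real-data users can pass accession-keyed
description maps or their own marker lists.

## Growth stoichiometry

The balance system for `1 substrate + a NH4+ + b O2 → c biomass +
d CO2 + e H2O + f H+` is solved in exact rational arithmetic with the
biomass coefficient fixed by the user-supplied yield (C-mol per mol
substrate); the solver never infers a yield. Order of solution:
N balance gives `a`, C balance `d`, charge balance `f = a` (for a
neutral substrate and biomass), H balance `e`, O balance `b`; the
redundant degree-of-reduction identity `γ_S = c·γ_X + 4b` with
`γ = 4C + H − 2O − 3N` (ammonium-as-N-source convention, making
γ = 4.2 for CH1.8O0.5N0.2) must close exactly and is asserted. Yields
outside `[0, C_substrate]` and any negative solved coefficient raise
an infeasibility error. Full precision is kept internally; rounding to
printed precision (3 decimals for NH4+/H+, 2 elsewhere) happens only
in reports. For the reference inputs the solver gives H+ = NH4+ =
0.656 by charge balance; a cited figure of 0.6 H+ alongside 0.656 NH4+
cannot satisfy the charge balance, and the solver reports the
balance-consistent value rather than matching the rounding.

## Pullulan digestion

Pullulan with `r` repeats has `3r` units and bonds
`(α1,4, α1,4, α1,6)` repeating, final α1,6 absent; unit 0 is the
non-reducing end and bond `i` joins units `i` and `i+1`. An enzyme is
a pure predicate on (bond type, predecessor type, successor type,
chain-end flags); exhaustive mode cuts every accepted bond, stochastic
mode cuts each independently with probability `p` under a seed
(identical seeds ⇒ identical spectra). Fragments are classified by
internal bond pattern; terminal fragments that are not full triads are
reported as their own species, never merged.

Preset specificities: neopullulanase cuts the α-1,4 bond whose
successor is α-1,6 or chain end (interior products panose,
α1,6–α1,4); isopullulanase cuts the α-1,4 whose predecessor is α-1,6
or chain start (isopanose, α1,4–α1,6) — the two are distinguishable
purely by product pattern, which the tests assert. Pullulanase II is
the unrestricted both-bond preset; exhaustive use gives glucose, a
model choice. The type III pullulan hydrolase is stochastic over
α-1,6 bonds *plus* the neo-position α-1,4 bonds: an unrestricted
any-bond rule would strand lone α-1,6 bonds and emit isomaltose,
which type III digests are not described to form; the restricted rule
yields exactly the glucose/maltose/maltotriose/panose set, and its
complete-digestion limit is glucose plus one maltose stub per repeat.
No quantitative promiscuity model is implemented — minor off-pattern
products of real enzymes have no stated rates to calibrate against.

## Synthetic data

The generator's defaults are the study conditions, not tuning knobs:

* **Enrichment scenario** — one dominant genus at a 70% target share
  of spectral counts over a 12-genus tail; 5% of ORFs unclassifiable.
  `dominant_weight` is defined as the *observable* share, so the
  underlying genus weight is inflated by `1/(1 − unclassifiable)` —
  otherwise the unclassified bucket would systematically depress the
  measured share below its nominal value.
* **Inoculum scenario** — 120 genera with a 0.98-geometric weight
  tail (chosen so all genera are likely drawn at desk scale, keeping
  the >100-genus condition) and 80% of ORFs carrying lineage-free
  hits, hence unassignable.
* **Roles** — secreted GH, intracellular GH (1:4, matching a
  17-vs-96-like split), glycolytic markers (3%), transporters (3%),
  housekeeping (rest). One secreted-GH ORF is planted as the
  amylopullulanase: supernatant mean 400 versus 40 for other secreted
  GHs, encoding the premise that the enzyme essential for growth on
  the sole carbon source is the most abundant secretome protein. The
  planted ORF belongs to the dominant genus for the same reason.
* **Counts** — negative-binomial with shape 8 per role × fraction;
  intracellular roles reach the supernatant only via
  `supernatant mean = lysis_rate × pellet mean` (default 0.02, the
  low-lysis regime); unique peptides are drawn ≤ count with most
  multi-count identifications passing the ≥2-peptide filter; a
  `depth` argument rescales all means to a target total count.
  The count model aims at structural realism (overdispersion,
  role/fraction structure), not at distributional fidelity to any
  instrument.

Desk scale is 2000 ORFs (a `--paper-scale` switch runs 14 000 for
stress tests); tests use 100–2000 ORFs depending on what they measure,
sized so the full suite stays fast while the statistics they assert
are stable. Identical seeds give byte-identical files; the metagenome
and expression stages use distinct seed streams so equal seeds cannot
correlate genus with expression.

What passing tests on this generator do **not** show: real spectral
counts are not negative-binomial with shared role means; real
lineages are not noise-free strings; real annotation coverage is not
independent of function; and the planted-abundance premise is an
assumption, not a law. The synthetic results validate the *pipeline
logic* (filters, votes, ranks, balances), not biological effect sizes.

## The packaged worked example

A 17-protein secretome candidate table ships as an in-package fixture:
accessions, molecular weights and InterPro entries as printed in its
source; spectral counts were published only as bar heights, so the
fixture carries arbitrary descending placeholder counts flagged
non-authoritative — nothing numeric is asserted about them beyond
presence and the ≥2-peptide criterion. Sequences are not public, so
the entries carry none and molecular weights are supplied as a map.

## Numerical choices

Exact rationals in the stoichiometry solver; integer count arithmetic
in composition; all sort keys carry an accession tiebreak so every
report is a strict total order and byte-stable under permutation;
composition closure is enforced to 1e-9 with deterministic drift
assignment; stochastic digestion and all generators take explicit
seeds.

## Known limitations

Signal-peptide or subcellular prediction is out of scope (external
predictions can be joined as columns); FDR is not recomputed;
lineage strings are taken as given (no taxonomy-database resolution);
digestion is equilibrium-free and kinetics-free; the pipeline consumes
annotator/aligner outputs and never invokes those tools itself.
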