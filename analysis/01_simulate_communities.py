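"""Generate the two synthetic study communities used by the later steps.

Writes, under results/data/:
  * ``inoculum/``   — high-diversity community (>100 genera, 80% of ORFs
    carrying no informative lineage), the pre-enrichment condition;
  * ``enrichment/`` — one genus dominating ~70% of spectral counts, with
    a planted extracellular amylopullulanase-like gene, the
    post-enrichment condition.

Both are desk-scale (2000 ORFs) and fully determined by the seed.
"""

from pathlib import Path

from ghmine import synthetic_data as sd

SEED = 1
OUT = Path("results/data")


def main() -> None:
    for scenario in ("inoculum", "enrichment"):
        manifest = sd.generate_dataset(OUT / scenario, scenario=scenario, n_orfs=2000, seed=SEED)
        print(f"{scenario}: {manifest['n_orfs']} ORFs -> {OUT / scenario}")
        if manifest["planted_top_secreted"]:
            print(f"  planted secreted amylopullulanase-like gene: {manifest['planted_top_secreted']}")


if __name__ == "__main__":
    main()
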