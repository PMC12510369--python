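"""Why the cultures acidify: the aerobic growth balance on glucose.

Solves 1 C6H12O6 + a NH4+ + b O2 -> c CH1.8N0.2O0.5 + d CO2 + e H2O + f H+
at a biomass yield of 3.28 C-mol per mol glucose and writes the
coefficients (with balance residuals) to results/tables/stoichiometry.json.
The charge balance forces f = a: every ammonium assimilated releases one
proton, which is the acidification an unbuffered culture shows.
"""

from pathlib import Path

from ghmine import stoichiometry as stoich

OUT = Path("results/tables")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    solved = stoich.solve(stoich.GLUCOSE, stoich.STANDARD_BIOMASS, "3.28")
    (OUT / "stoichiometry.json").write_text(solved.to_json() + "\n", encoding="utf-8")
    print(solved.equation())
    print(
        f"protons released per mol glucose: {stoich.protons_per_substrate(solved):.3f} "
        "(equals the ammonium uptake by charge balance)"
    )
    combustion = stoich.solve(stoich.GLUCOSE, stoich.STANDARD_BIOMASS, 0)
    print("zero-yield limit (combustion):", combustion.equation())


if __name__ == "__main__":
    main()
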