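"""Aerobic growth stoichiometry on a CHON substrate with ammonium nitrogen.

Solves the element and charge balances of

    1 substrate + a NH4+ + b O2  →  c biomass + d CO2 + e H2O + f H+

for a fixed biomass coefficient ``c`` (C-mol biomass per mol substrate,
an input — it is never inferred).  With biomass written per C-mol
(e.g. CH1.8O0.5N0.2) the balances close in sequence:

    N:      a = c·n_X
    C:      d = C_S − c·C_X
    charge: f = a                      (NH4+ in, H+ out)
    H:      H_S + 4a = c·H_X + 2e + f
    O:      O_S + 2b = c·O_X + 2d + e

so every mole of ammonium assimilated releases one proton — the
acidification of an unbuffered culture growing on a neutral sugar.
The redundant degree-of-reduction balance γ_S = c·γ_X + 4b, with
γ = 4C + H − 2O − 3N (ammonium-as-N-source convention), is verified
independently.  All arithmetic is exact rational; floats only appear
when reporting.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Union

Number = Union[int, float, str, Fraction]

_FORMULA_TOKEN = re.compile(r"([CHON])(\d+(?:\.\d+)?|)")


def _frac(x: Number) -> Fraction:
    return x if isinstance(x, Fraction) else Fraction(str(x))


@dataclass(frozen=True)
class ElementalFormula:
    """Atoms of C, H, O, N per formula unit plus net charge (exact rationals)."""

    c: Fraction
    h: Fraction
    o: Fraction
    n: Fraction
    charge: Fraction = Fraction(0)

    def __post_init__(self) -> None:
        for value in (self.c, self.h, self.o, self.n):
            if value < 0:
                raise ValueError("negative atom count")
        if self.c == self.h == self.o == self.n == 0:
            raise ValueError("formula has no atoms")

    @classmethod
    def of(cls, c: Number = 0, h: Number = 0, o: Number = 0, n: Number = 0,
           charge: Number = 0) -> "ElementalFormula":
        return cls(_frac(c), _frac(h), _frac(o), _frac(n), _frac(charge))

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse strings like "C6H12O6" or "CH1.8O0.5N0.2"; decimals exact.

        A trailing '+' or '-' (optionally preceded by a digit) sets charge.
        """
        body = text.strip()
        charge = Fraction(0)
        m = re.search(r"([+-]+)$", body)  # "+", "-", "++", ... (digits belong to atoms)
        if m:
            signs = m.group(1)
            if len(set(signs)) > 1:
                raise ValueError(f"cannot parse charge in {text!r}")
            charge = Fraction(len(signs) if signs[0] == "+" else -len(signs))
            body = body[: m.start()]
        counts = {"C": Fraction(0), "H": Fraction(0), "O": Fraction(0), "N": Fraction(0)}
        consumed = 0
        for match in _FORMULA_TOKEN.finditer(body):
            if match.start() != consumed:
                raise ValueError(f"cannot parse formula {text!r}")
            counts[match.group(1)] += Fraction(match.group(2) or "1")
            consumed = match.end()
        if consumed != len(body):
            raise ValueError(f"cannot parse formula {text!r}")
        return cls(counts["C"], counts["H"], counts["O"], counts["N"], charge)

    @property
    def degree_of_reduction(self) -> Fraction:
        """γ = 4C + H − 2O − 3N (electrons per formula unit, NH4+ N source)."""
        return 4 * self.c + self.h - 2 * self.o - 3 * self.n


GLUCOSE = ElementalFormula.parse("C6H12O6")
STANDARD_BIOMASS = ElementalFormula.parse("CH1.8O0.5N0.2")


@dataclass(frozen=True)
class GrowthStoichiometry:
    """Solved coefficients on a 1-mol-substrate basis (exact rationals)."""

    substrate: ElementalFormula
    biomass_formula: ElementalFormula
    nh4_coeff: Fraction
    o2_coeff: Fraction
    biomass_coeff: Fraction
    co2_coeff: Fraction
    h2o_coeff: Fraction
    hplus_coeff: Fraction

    @property
    def residuals(self) -> Mapping[str, float]:
        """Closure error of each balance (floats; exactly solvable system)."""
        s, x = self.substrate, self.biomass_formula
        a, b, c = self.nh4_coeff, self.o2_coeff, self.biomass_coeff
        d, e, f = self.co2_coeff, self.h2o_coeff, self.hplus_coeff
        return {
            "C": float(s.c - c * x.c - d),
            "H": float(s.h + 4 * a - c * x.h - 2 * e - f),
            "O": float(s.o + 2 * b - c * x.o - 2 * d - e),
            "N": float(s.n + a - c * x.n),
            "charge": float(s.charge + a - c * x.charge - f),
            "electron": float(
                s.degree_of_reduction - c * x.degree_of_reduction - 4 * b
            ),
        }

    def as_dict(self, ndigits: int = 6) -> dict:
        return {
            "substrate": 1.0,
            "NH4+": round(float(self.nh4_coeff), ndigits),
            "O2": round(float(self.o2_coeff), ndigits),
            "biomass": round(float(self.biomass_coeff), ndigits),
            "CO2": round(float(self.co2_coeff), ndigits),
            "H2O": round(float(self.h2o_coeff), ndigits),
            "H+": round(float(self.hplus_coeff), ndigits),
            "residuals": {k: v for k, v in self.residuals.items()},
        }

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=1)

    def equation(self) -> str:
        """Human-readable equation at conventional printed precision."""
        return (
            f"1 substrate + {float(self.nh4_coeff):.3f} NH4+ + "
            f"{float(self.o2_coeff):.2f} O2 -> "
            f"{float(self.biomass_coeff):.2f} biomass + "
            f"{float(self.co2_coeff):.2f} CO2 + {float(self.h2o_coeff):.2f} H2O + "
            f"{float(self.hplus_coeff):.3f} H+"
        )


def solve(
    substrate: ElementalFormula,
    biomass: ElementalFormula,
    biomass_yield_c: Number,
) -> GrowthStoichiometry:
    """Solve the growth balance for a given biomass yield.

    ``biomass_yield_c`` is in C-mol biomass per mol substrate; the
    biomass *coefficient* is yield divided by the biomass formula's
    carbon content (identical when the formula is per C-mol).  Yield 0
    is complete combustion.  A yield exceeding substrate carbon, or any
    negative solved coefficient, is infeasible.
    """
    yield_c = _frac(biomass_yield_c)
    if substrate.c <= 0:
        raise ValueError("substrate must contain carbon")
    if biomass.c <= 0:
        raise ValueError("biomass formula must contain carbon")
    if yield_c < 0 or yield_c > substrate.c:
        raise ValueError(
            f"biomass yield {float(yield_c)} C-mol outside [0, {float(substrate.c)}]"
        )
    c = yield_c / biomass.c
    a = c * biomass.n - substrate.n
    d = substrate.c - c * biomass.c
    f = substrate.charge + a - c * biomass.charge
    e = (substrate.h + 4 * a - c * biomass.h - f) / 2
    b = (c * biomass.o + 2 * d + e - substrate.o) / 2

    stoich = GrowthStoichiometry(
        substrate=substrate,
        biomass_formula=biomass,
        nh4_coeff=a,
        o2_coeff=b,
        biomass_coeff=c,
        co2_coeff=d,
        h2o_coeff=e,
        hplus_coeff=f,
    )
    for name, value in [("NH4+", a), ("O2", b), ("CO2", d), ("H2O", e), ("H+", f)]:
        if value < 0:
            raise ValueError(f"infeasible yield: {name} coefficient {float(value)} < 0")
    # Redundant electron balance must close exactly; a failure here is a bug.
    assert stoich.residuals["electron"] == 0.0
    assert stoich.residuals["O"] == 0.0
    return stoich


def protons_per_substrate(stoich: GrowthStoichiometry) -> float:
    """Mol H+ released per mol substrate consumed (equals the NH4+ uptake
    for a neutral substrate and neutral biomass, by charge balance)."""
    return float(stoich.hplus_coeff)
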