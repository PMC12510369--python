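"""Pullulan cleavage-rule simulator.

Pullulan is modeled as a linear chain of glucose units whose n−1
inter-unit bonds are each α-1,4 or α-1,6: a chain of r maltotriose
repeats has 3r units and the repeating bond pattern (α1,4, α1,4, α1,6)
with the final α1,6 absent.  Unit 0 is the non-reducing end; bond i
joins unit i to unit i+1.

An enzyme is a pure predicate on a bond's local context (its type, the
neighbouring bond types, and chain-end flags).  Exhaustive digestion
cuts every bond the predicate accepts; stochastic digestion cuts each
accepted bond independently with probability p under a seed.  Products
are classified by their internal bond pattern:

    ()            glucose        (α1,4)        maltose
    (α1,6)        isomaltose     (α1,4, α1,4)  maltotriose
    (α1,6, α1,4)  panose         (α1,4, α1,6)  isopanose

and anything longer/other as ``Hex{n}-other``.  Hexose count is
conserved by construction for every enzyme and mode.

Presets follow the classical pullulan-enzyme typology: pullulanases cut
α-1,6 (type I) or both bond types (type II); pullulan hydrolases cut
α-1,4 next to an α-1,6 — type I (neopullulanase, successor-side, panose)
and type II (isopullulanase, predecessor-side, isopanose) — while
type III attacks both bond types.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

A14 = "alpha-1,4"
A16 = "alpha-1,6"
BOND_TYPES = (A14, A16)

SPECIES_NAMES = {
    (): "glucose",
    (A14,): "maltose",
    (A16,): "isomaltose",
    (A14, A14): "maltotriose",
    (A16, A14): "panose",
    (A14, A16): "isopanose",
}


@dataclass(frozen=True)
class GlycanChain:
    """A linear glucan: n_units glucoses joined by n_units−1 typed bonds."""

    n_units: int
    bonds: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("chain needs at least one unit")
        if len(self.bonds) != self.n_units - 1:
            raise ValueError("bond count must be n_units - 1")
        if any(b not in BOND_TYPES for b in self.bonds):
            raise ValueError("unknown bond type")


@dataclass(frozen=True)
class BondContext:
    """Local context a cleavage predicate may inspect."""

    bond_type: str
    prev_type: Optional[str]  # None at the non-reducing chain start
    next_type: Optional[str]  # None at the reducing chain end


@dataclass(frozen=True)
class EnzymeRule:
    """Named cleavage specificity; ``cleaves`` must be a pure function."""

    name: str
    cleaves: Callable[[BondContext], bool]
    mode: str = "exhaustive"  # exhaustive | stochastic
    p: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("exhaustive", "stochastic"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("cut probability must be in [0, 1]")


def pullulanase_i() -> EnzymeRule:
    """Type I pullulanase: cleaves every α-1,6 bond → maltotriose from pullulan."""
    return EnzymeRule("pullulanase-I", lambda ctx: ctx.bond_type == A16)


def pullulanase_ii() -> EnzymeRule:
    """Type II pullulanase (amylopullulanase): cleaves both bond types."""
    return EnzymeRule("pullulanase-II", lambda ctx: True)


def neopullulanase() -> EnzymeRule:
    """Pullulan hydrolase type I: cuts the α-1,4 bond whose successor is
    α-1,6 or the chain end; interior products are panose (α1,6-α1,4)."""
    return EnzymeRule(
        "neopullulanase",
        lambda ctx: ctx.bond_type == A14 and ctx.next_type in (A16, None),
    )


def isopullulanase() -> EnzymeRule:
    """Pullulan hydrolase type II: cuts the α-1,4 bond whose predecessor is
    α-1,6 or the chain start; interior products are isopanose (α1,4-α1,6)."""
    return EnzymeRule(
        "isopullulanase",
        lambda ctx: ctx.bond_type == A14 and ctx.prev_type in (A16, None),
    )


def pullulan_hydrolase_iii(p: float = 0.5) -> EnzymeRule:
    """Pullulan hydrolase type III: attacks both bond types, modeled
    stochastically as cutting α-1,6 bonds and the α-1,4 bonds adjacent
    to an α-1,6 on the reducing side (or chain end).  Partial digests of
    pullulan then yield exactly the panose / maltotriose / maltose /
    glucose mixture (an unrestricted any-bond rule would also strand
    lone α-1,6 bonds and emit isomaltose, which type III digests are
    not reported to form), converging to all-glucose as p→1."""
    return EnzymeRule(
        "pullulan-hydrolase-III",
        lambda ctx: ctx.bond_type == A16
        or (ctx.bond_type == A14 and ctx.next_type in (A16, None)),
        mode="stochastic",
        p=p,
    )


PRESETS: dict[str, Callable[..., EnzymeRule]] = {
    "pullulanase-I": pullulanase_i,
    "pullulanase-II": pullulanase_ii,
    "neopullulanase": neopullulanase,
    "isopullulanase": isopullulanase,
    "pullulan-hydrolase-III": pullulan_hydrolase_iii,
}


def build_pullulan(n_repeats: int) -> GlycanChain:
    """Pullulan of ``n_repeats`` maltotriose repeats (3·n units)."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    bonds = ((A14, A14, A16) * n_repeats)[:-1]
    return GlycanChain(n_units=3 * n_repeats, bonds=tuple(bonds))


@dataclass(frozen=True)
class ProductSpectrum:
    """Digestion products: counts per internal bond pattern."""

    counts: tuple[tuple[tuple[str, ...], int], ...]

    @classmethod
    def from_fragments(cls, fragments: list[tuple[str, ...]]) -> "ProductSpectrum":
        counter = Counter(fragments)
        return cls(tuple(sorted(counter.items())))

    @property
    def total_units(self) -> int:
        return sum((len(pattern) + 1) * count for pattern, count in self.counts)

    def species_counts(self) -> dict[str, int]:
        """Counts keyed by species name (non-canonical patterns → Hex{n}-other)."""
        named: Counter[str] = Counter()
        for pattern, count in self.counts:
            named[SPECIES_NAMES.get(pattern, f"Hex{len(pattern) + 1}-other")] += count
        return dict(named)

    def length_counts(self) -> dict[int, int]:
        lengths: Counter[int] = Counter()
        for pattern, count in self.counts:
            lengths[len(pattern) + 1] += count
        return dict(lengths)


def digest(
    chain: GlycanChain, enzyme: EnzymeRule, seed: Optional[int] = None
) -> ProductSpectrum:
    """Cut the chain under the enzyme's rule and classify the fragments.

    In stochastic mode each predicate-accepted bond is cut independently
    with probability ``enzyme.p``; identical seeds give identical spectra.
    """
    bonds = chain.bonds
    eligible = [
        i
        for i in range(len(bonds))
        if enzyme.cleaves(
            BondContext(
                bond_type=bonds[i],
                prev_type=bonds[i - 1] if i > 0 else None,
                next_type=bonds[i + 1] if i + 1 < len(bonds) else None,
            )
        )
    ]
    if enzyme.mode == "stochastic":
        rng = np.random.default_rng(seed)
        draws = rng.random(len(eligible))
        cuts = {i for i, u in zip(eligible, draws) if u < enzyme.p}
    else:
        cuts = set(eligible)

    fragments: list[tuple[str, ...]] = []
    current: list[str] = []
    for i, bond in enumerate(bonds):
        if i in cuts:
            fragments.append(tuple(current))
            current = []
        else:
            current.append(bond)
    fragments.append(tuple(current))
    return ProductSpectrum.from_fragments(fragments)


def hexose_histogram(spectrum: ProductSpectrum) -> tuple[dict[int, float], int]:
    """Fraction of product molecules per hexose length, plus the dominant
    length (ties break to the smaller length)."""
    lengths = spectrum.length_counts()
    if not lengths:
        raise ValueError("empty product spectrum")
    total = sum(lengths.values())
    fractions = {length: count / total for length, count in sorted(lengths.items())}
    dominant = max(fractions, key=lambda length: (fractions[length], -length))
    return fractions, dominant


def write_spectrum_tsv(spectrum: ProductSpectrum, path) -> None:
    total = sum(count for _, count in spectrum.counts)
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("# unit 0 = non-reducing end; bond i joins units i and i+1\n")
        handle.write("species\tbond_pattern\tlength\tcount\tfraction\n")
        for pattern, count in spectrum.counts:
            name = SPECIES_NAMES.get(pattern, f"Hex{len(pattern) + 1}-other")
            handle.write(
                f"{name}\t{','.join(pattern) or '-'}\t{len(pattern) + 1}\t"
                f"{count}\t{count / total:.6f}\n"
            )
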