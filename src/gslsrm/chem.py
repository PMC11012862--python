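"""Elemental-composition arithmetic and monoisotopic mass/m-z computation.

Glycosphingolipid (GSL) analytes are assembled from dehydro-residue
building blocks (the mass a monosaccharide adds per glycosidic
attachment) plus a ceramide, so neutral masses are plain element-wise
sums with no further water correction.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "ATOMIC_MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "ElementComposition",
    "MonosaccharideResidue",
    "SphingoidBase",
    "FattyAcyl",
    "Ceramide",
    "GlycanHeadgroup",
    "GSLSpecies",
    "RESIDUES",
    "D18_1",
    "monoisotopic_mass",
    "neutral_mass",
    "mz_deprotonated",
    "neuac_fragment_mz",
]

#: Monoisotopic atomic masses (Da). Extensible: unknown symbols raise.
ATOMIC_MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
}

#: Proton mass used for deprotonation. The electron mass (0.00055 Da) is
#: neglected; the difference is invisible at one-decimal m/z reporting.
PROTON_MASS = 1.00727646


class CompositionError(ValueError):
    """Raised for negative element counts or unknown element symbols."""


@dataclass(frozen=True)
class ElementComposition:
    """Integer element counts, e.g. ``ElementComposition({"C": 6, "H": 10, "O": 5})``.

    Supports ``+`` and ``-``; subtraction that would drive any count
    negative raises :class:`CompositionError`.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {el: int(n) for el, n in self.counts.items() if n != 0}
        for el, n in clean.items():
            if n < 0:
                raise CompositionError(f"negative count for element {el!r}: {n}")
        object.__setattr__(self, "counts", clean)

    def __add__(self, other: "ElementComposition") -> "ElementComposition":
        merged = Counter(self.counts)
        merged.update(other.counts)
        return ElementComposition(dict(merged))

    def __sub__(self, other: "ElementComposition") -> "ElementComposition":
        merged = Counter(self.counts)
        merged.subtract(other.counts)
        return ElementComposition(dict(merged))

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __bool__(self) -> bool:
        return bool(self.counts)

    @classmethod
    def from_formula_counts(cls, **counts: int) -> "ElementComposition":
        """Build from keyword counts: ``ElementComposition.from_formula_counts(C=6, H=10, O=5)``."""
        return cls(counts)

    def formula(self) -> str:
        """Hill-ordered formula string (C, H, then alphabetical)."""
        order = sorted(self.counts, key=lambda e: (e != "C", e != "H", e))
        return "".join(f"{el}{self.counts[el]}" if self.counts[el] != 1 else el for el in order)


def _comp(**counts: int) -> ElementComposition:
    return ElementComposition(counts)


def add_compositions(a: ElementComposition, b: ElementComposition) -> ElementComposition:
    """Element-wise sum of two compositions (commutative, associative)."""
    return a + b


def monoisotopic_mass(composition: ElementComposition) -> float:
    """Monoisotopic mass in Da: sum of count x atomic monoisotopic mass.

    Raises
    ------
    CompositionError
        If the composition contains an element symbol not present in
        :data:`ATOMIC_MONOISOTOPIC_MASS`.
    """
    total = 0.0
    for element, count in composition.counts.items():
        try:
            total += count * ATOMIC_MONOISOTOPIC_MASS[element]
        except KeyError:
            raise CompositionError(
                f"no monoisotopic mass known for element symbol {element!r}"
            ) from None
    return total


@dataclass(frozen=True)
class MonosaccharideResidue:
    """A dehydro monosaccharide residue (mass added per glycosidic bond)."""

    name: str
    composition: ElementComposition


#: Mass-degenerate residue catalog: Glc/Gal collapse to Hex, GlcNAc/GalNAc
#: to HexNAc. All compositions are dehydro residues, not free sugars.
RESIDUES: dict[str, MonosaccharideResidue] = {
    "Hex": MonosaccharideResidue("Hex", _comp(C=6, H=10, O=5)),
    "HexNAc": MonosaccharideResidue("HexNAc", _comp(C=8, H=13, N=1, O=5)),
    "NeuAc": MonosaccharideResidue("NeuAc", _comp(C=11, H=17, N=1, O=8)),
    "dHex": MonosaccharideResidue("dHex", _comp(C=6, H=10, O=4)),
}

_WATER = _comp(H=2, O=1)


@dataclass(frozen=True)
class SphingoidBase:
    """A free sphingoid base, e.g. sphingosine d18:1 = C18H37NO2."""

    shorthand: str
    composition: ElementComposition


#: Default sphingoid base: 18-carbon sphingosine.
D18_1 = SphingoidBase("d18:1", _comp(C=18, H=37, N=1, O=2))


@dataclass(frozen=True)
class FattyAcyl:
    """A fatty-acyl chain given as carbons:double-bonds (free-acid composition C_c H_(2c-2d) O2)."""

    carbons: int
    double_bonds: int

    def __post_init__(self) -> None:
        if not 14 <= self.carbons <= 30:
            raise ValueError(f"acyl carbon count {self.carbons} outside supported range 14-30")
        if not 0 <= self.double_bonds <= self.carbons // 2:
            raise ValueError(
                f"double-bond count {self.double_bonds} invalid for {self.carbons} carbons"
            )

    @property
    def shorthand(self) -> str:
        return f"{self.carbons}:{self.double_bonds}"

    @classmethod
    def from_shorthand(cls, text: str) -> "FattyAcyl":
        c, _, d = text.partition(":")
        return cls(int(c), int(d))

    @property
    def composition(self) -> ElementComposition:
        """Free fatty-acid composition."""
        return _comp(C=self.carbons, H=2 * self.carbons - 2 * self.double_bonds, O=2)


@dataclass(frozen=True)
class Ceramide:
    """Sphingoid base amide-linked to a fatty acyl (base + free acid - H2O)."""

    base: SphingoidBase
    acyl: FattyAcyl

    @property
    def shorthand(self) -> str:
        return f"{self.base.shorthand}/{self.acyl.shorthand}"

    @property
    def composition(self) -> ElementComposition:
        return self.base.composition + self.acyl.composition - _WATER


@dataclass(frozen=True)
class GlycanHeadgroup:
    """Residue counts of an acidic glycan headgroup (>= 1 NeuAc).

    ``series`` and any structural (SNFG) detail are display annotations
    only; masses depend solely on the residue counts.
    """

    name: str
    n_hex: int = 0
    n_hexnac: int = 0
    n_neuac: int = 0
    n_dhex: int = 0
    series: str = ""

    def __post_init__(self) -> None:
        for attr in ("n_hex", "n_hexnac", "n_neuac", "n_dhex"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be non-negative")
        if self.n_neuac < 1:
            raise ValueError(
                f"glycan {self.name!r} has no NeuAc; only acidic glycans are supported"
            )

    @property
    def residue_key(self) -> tuple[int, int, int, int]:
        """(Hex, HexNAc, NeuAc, dHex) counts — isomeric glycans share this key."""
        return (self.n_hex, self.n_hexnac, self.n_neuac, self.n_dhex)

    @property
    def composition(self) -> ElementComposition:
        comp = ElementComposition()
        for count, residue in (
            (self.n_hex, RESIDUES["Hex"]),
            (self.n_hexnac, RESIDUES["HexNAc"]),
            (self.n_neuac, RESIDUES["NeuAc"]),
            (self.n_dhex, RESIDUES["dHex"]),
        ):
            for _ in range(count):
                comp = comp + residue.composition
        return comp


@dataclass(frozen=True)
class GSLSpecies:
    """One enumerated analyte: glycan headgroup + ceramide."""

    glycan: GlycanHeadgroup
    ceramide: Ceramide

    @property
    def name(self) -> str:
        return f"{self.glycan.name} ({self.ceramide.shorthand})"

    @property
    def composition(self) -> ElementComposition:
        # residues are pre-dehydrated: plain sum, no water correction
        return self.glycan.composition + self.ceramide.composition


def neutral_mass(species: GSLSpecies) -> float:
    """Neutral monoisotopic mass of a GSL species in Da."""
    return monoisotopic_mass(species.composition)


def mz_deprotonated(neutral: float, z: int) -> float:
    """m/z of the [M-zH]^z- ion: (neutral - z x proton) / z."""
    if z <= 0:
        raise ValueError(f"charge must be a positive integer, got {z}")
    if neutral <= z * PROTON_MASS:
        raise ValueError(f"neutral mass {neutral} too small for charge {z}")
    return (neutral - z * PROTON_MASS) / z


def neuac_fragment_mz() -> float:
    """m/z of the deprotonated NeuAc residue anion (~290.09, nominal 290).

    This sialic-acid fragment is the species-independent product ion
    shared by every transition.
    """
    return monoisotopic_mass(RESIDUES["NeuAc"].composition) - PROTON_MASS


def round_mz(mz: float, decimals: int = 1) -> float:
    """Report-rounding convention for m/z values (nearest, one decimal)."""
    return round(mz, decimals)
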