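"""Elemental formula arithmetic and negative-mode ion m/z computation.

All m/z values in this package are monoisotopic and electron-inclusive:
the mass of the attached electron (0.000549 Da) is added to every anion,
which is what high-resolution instruments calibrated on ion masses report.
The diagnostic-fragment registry maps compound-class tags (bile-acid
conjugation groups, lysophospholipid head groups, fatty acyl chains) to
the fragment ions those classes produce under all-ion fragmentation.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field
from functools import lru_cache

__all__ = [
    "ELECTRON_MASS",
    "C13_C12_DELTA",
    "Formula",
    "IonSpecies",
    "DiagnosticFragment",
    "Adduct",
    "parse_formula",
    "monoisotopic_mass",
    "ion_mz",
    "ppm_window",
    "isotope_m1",
    "fragment_registry",
    "acyl_formula",
    "lpl_formula",
    "LPL_CLASS_INFO",
]

ELECTRON_MASS = 0.000548579909
#: 13C - 12C mass difference, the spacing of the M+1 isotopologue for CHNOPS.
C13_C12_DELTA = 1.0033548378


def _load_element_masses() -> dict[str, float]:
    masses: dict[str, float] = {}
    ref = importlib.resources.files("aifquant.data").joinpath("elements.tsv")
    for line in ref.read_text().splitlines():
        if not line or line.startswith("#") or line.startswith("symbol"):
            continue
        symbol, mass = line.split("\t")[:2]
        masses[symbol] = float(mass)
    return masses


ELEMENT_MASSES: dict[str, float] = _load_element_masses()

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class Formula:
    """Elemental composition with non-negative counts.

    Only elements with a defined monoisotopic mass are accepted; ``D`` is
    deuterium, treated as its own pseudo-element so that labelled internal
    standards (CA-d5 etc.) are first-class formulas.
    """

    element_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for symbol, count in self.element_counts.items():
            if symbol not in ELEMENT_MASSES:
                raise ValueError(f"unknown element symbol: {symbol!r}")
            if count < 0:
                raise ValueError(f"negative count for element {symbol}: {count}")
            if count:
                clean[symbol] = int(count)
        object.__setattr__(self, "element_counts", clean)

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)

    def __add__(self, other: "Formula") -> "Formula":
        counts = dict(self.element_counts)
        for symbol, count in other.element_counts.items():
            counts[symbol] = counts.get(symbol, 0) + count
        return Formula(counts)

    def __sub__(self, other: "Formula") -> "Formula":
        counts = dict(self.element_counts)
        for symbol, count in other.element_counts.items():
            counts[symbol] = counts.get(symbol, 0) - count
        return Formula(counts)  # __post_init__ rejects negatives

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical (D rendered after H).
        counts = dict(self.element_counts)
        parts = []
        for symbol in ("C", "H", "D"):
            if symbol in counts:
                n = counts.pop(symbol)
                parts.append(symbol + (str(n) if n > 1 else ""))
        for symbol in sorted(counts):
            n = counts[symbol]
            parts.append(symbol + (str(n) if n > 1 else ""))
        return "".join(parts)

    def __bool__(self) -> bool:
        return bool(self.element_counts)


def parse_formula(text: str) -> Formula:
    """Parse a Hill-style composition string such as ``"C24H40O5"``.

    Raises ``ValueError`` naming the offending symbol for anything that is
    not a known element, so malformed library rows fail loudly.
    """
    if not isinstance(text, str) or not text.strip():
        raise ValueError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise ValueError(f"cannot parse formula {text!r} at position {pos}")
        symbol, digits = m.groups()
        if symbol not in ELEMENT_MASSES:
            raise ValueError(f"unknown element symbol: {symbol!r} in {text!r}")
        counts[symbol] = counts.get(symbol, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return Formula(counts)


def monoisotopic_mass(f: Formula) -> float:
    """Sum of count x most-abundant-isotope mass; 12C anchors the scale."""
    return sum(ELEMENT_MASSES[s] * n for s, n in f.element_counts.items())


class Adduct:
    """Negative-mode adduct kinds supported by the acquisition."""

    DEPROTONATED = "[M-H]-"
    ACETATE = "[M+CH3COO]-"
    ANION = "anion"  # formula already describes the charged species

    ALL = (DEPROTONATED, ACETATE, ANION)


_PROTON_LOSS = ELEMENT_MASSES["H"]
_ACETATE_MASS = None  # computed lazily to avoid order issues


def _acetate_mass() -> float:
    global _ACETATE_MASS
    if _ACETATE_MASS is None:
        _ACETATE_MASS = monoisotopic_mass(parse_formula("C2H3O2"))
    return _ACETATE_MASS


@dataclass(frozen=True)
class IonSpecies:
    neutral_formula: Formula
    adduct: str
    mz: float
    charge: int = -1

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("ion m/z must be positive")


def ion_mz(neutral: Formula, adduct: str = Adduct.DEPROTONATED) -> IonSpecies:
    """m/z of the singly charged anion of ``neutral`` for the given adduct.

    [M-H]-  : M - m(H) + m(e)
    acetate : M + m(CH3COO) + m(e)
    anion   : the formula is already the ion's composition; + m(e)
    """
    m = monoisotopic_mass(neutral)
    if adduct == Adduct.DEPROTONATED:
        mz = m - _PROTON_LOSS + ELECTRON_MASS
    elif adduct == Adduct.ACETATE:
        mz = m + _acetate_mass() + ELECTRON_MASS
    elif adduct == Adduct.ANION:
        mz = m + ELECTRON_MASS
    else:
        raise ValueError(f"unsupported adduct kind: {adduct!r}")
    return IonSpecies(neutral_formula=neutral, adduct=adduct, mz=mz)


def ppm_window(mz: float, tol_ppm: float) -> tuple[float, float]:
    """Closed interval [mz*(1-tol*1e-6), mz*(1+tol*1e-6)]."""
    if mz <= 0:
        raise ValueError("m/z must be positive")
    if tol_ppm <= 0:
        raise ValueError("ppm tolerance must be positive")
    return mz * (1.0 - tol_ppm * 1e-6), mz * (1.0 + tol_ppm * 1e-6)


def isotope_m1(mz: float) -> float:
    """m/z of the M+1 isotopologue of a singly charged ion (one 13C)."""
    if mz <= 0:
        raise ValueError("m/z must be positive")
    return mz + C13_C12_DELTA


@dataclass(frozen=True)
class DiagnosticFragment:
    """A class-diagnostic fragment: either an anion composition with its
    m/z, or a neutral loss (no observable m/z of its own)."""

    name: str
    applies_to: str
    ion_composition: Formula | None = None
    neutral_loss: Formula | None = None
    mz: float | None = None

    def __post_init__(self) -> None:
        if (self.ion_composition is None) == (self.neutral_loss is None):
            raise ValueError("exactly one of ion_composition / neutral_loss required")
        if self.ion_composition is not None and self.mz is None:
            object.__setattr__(
                self, "mz", ion_mz(self.ion_composition, Adduct.ANION).mz
            )


_ACYL_TAG = re.compile(r"^fatty-acyl\((\d+):(\d+)\)$")


def acyl_formula(carbons: int, double_bonds: int) -> Formula:
    """Carboxylate anion composition of a C:db fatty acyl chain,
    CnH(2n-2db-1)O2 (e.g. 16:0 -> C16H31O2)."""
    if carbons < 2 or double_bonds < 0 or 2 * carbons - 2 * double_bonds - 1 <= 0:
        raise ValueError(f"implausible acyl chain {carbons}:{double_bonds}")
    return Formula({"C": carbons, "H": 2 * carbons - 2 * double_bonds - 1, "O": 2})


@lru_cache(maxsize=None)
def _static_registry() -> dict[str, tuple[DiagnosticFragment, ...]]:
    registry: dict[str, list[DiagnosticFragment]] = {}
    ref = importlib.resources.files("aifquant.data").joinpath("fragments.tsv")
    lines = ref.read_text().splitlines()
    header = lines[0].split("\t")
    for line in lines[1:]:
        if not line or line.startswith("#"):
            continue
        row = dict(zip(header, line.split("\t")))
        ion = parse_formula(row["ion_composition"]) if row["ion_composition"] else None
        loss = parse_formula(row["neutral_loss"]) if row["neutral_loss"] else None
        frag = DiagnosticFragment(
            name=row["name"],
            applies_to=row["class_tag"],
            ion_composition=ion,
            neutral_loss=loss,
        )
        registry.setdefault(row["class_tag"], []).append(frag)
    return {tag: tuple(frags) for tag, frags in registry.items()}


# Lyso-glycerophospholipid composition: class backbone + acyl chain.
# formula = C(a+n) H(b+2n-2d) <heteroatoms> for an n:d chain; anchored on
# LPC 16:0 = C24H50NO7P, LPE 18:2 = C23H44NO7P, LPI 16:0 = C25H49O12P etc.
_LPL_BACKBONES: dict[str, tuple[int, int, dict[str, int]]] = {
    "LPC": (8, 18, {"N": 1, "O": 7, "P": 1}),
    "O-LPC": (8, 20, {"N": 1, "O": 6, "P": 1}),  # ether-linked, no carbonyl
    "LPE": (5, 12, {"N": 1, "O": 7, "P": 1}),
    "LPI": (9, 17, {"O": 12, "P": 1}),
    "LPS": (6, 12, {"N": 1, "O": 9, "P": 1}),
    "LPG": (6, 13, {"O": 9, "P": 1}),
}

#: head-group class tag and adduct rule per LPL class (choline -> acetate)
LPL_CLASS_INFO: dict[str, tuple[str, str]] = {
    "LPC": ("LPL-headgroup-PC", Adduct.ACETATE),
    "O-LPC": ("LPL-headgroup-PC", Adduct.ACETATE),
    "LPE": ("LPL-headgroup-PE", Adduct.DEPROTONATED),
    "LPI": ("LPL-headgroup-PI", Adduct.DEPROTONATED),
    "LPS": ("LPL-headgroup-PS", Adduct.DEPROTONATED),
    "LPG": ("LPL-headgroup-PG", Adduct.DEPROTONATED),
}


def lpl_formula(lpl_class: str, carbons: int, double_bonds: int) -> Formula:
    """Neutral composition of a lysophospholipid with one n:d acyl (or, for
    O-LPC, alkyl) chain."""
    if lpl_class not in _LPL_BACKBONES:
        raise ValueError(f"unknown LPL class: {lpl_class!r}")
    a, b, hetero = _LPL_BACKBONES[lpl_class]
    h = b + 2 * carbons - 2 * double_bonds
    counts = {"C": a + carbons, "H": h, **hetero}
    return Formula(counts)


def fragment_registry(class_tag: str) -> list[DiagnosticFragment]:
    """Diagnostic fragments registered for a compound-class tag.

    Static tags (conjugation groups, LPL head groups) come from the shipped
    TSV resource; ``fatty-acyl(C:db)`` tags are computed on demand from the
    carboxylate composition.
    """
    m = _ACYL_TAG.match(class_tag)
    if m:
        carbons, db = int(m.group(1)), int(m.group(2))
        return [
            DiagnosticFragment(
                name=f"FA {carbons}:{db} carboxylate",
                applies_to=class_tag,
                ion_composition=acyl_formula(carbons, db),
            )
        ]
    static = _static_registry()
    if class_tag not in static:
        raise KeyError(f"unknown compound class tag: {class_tag!r}")
    return list(static[class_tag])
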