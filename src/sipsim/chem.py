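"""Element and isotope reference data, formula parsing, and mass arithmetic.

Every simulation in this package is driven by an :class:`IsotopeTable` — a
per-element list of (nucleon number, exact mass, abundance) triples.  Stable
isotope probing (SIP) experiments replace the natural abundance of one heavy
isotope (e.g. 1.07 atom % for 13C) with an arbitrary user-chosen atom
fraction; :func:`apply_enrichment` performs that substitution while keeping
each element's abundances normalized.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

__all__ = [
    "PROTON_MASS",
    "Isotope",
    "IsotopeTable",
    "EnrichmentSpec",
    "IonSpec",
    "FormulaError",
    "parse_formula",
    "formula_to_string",
    "parse_enrichment",
    "apply_enrichment",
    "monoisotopic_mass",
    "expected_mass",
    "mz_from_neutral",
    "neutral_from_mz",
    "natural_table",
]

#: Mass of a proton in Da, used for (de)protonation charging.
PROTON_MASS = 1.007276466

Formula = dict  # element symbol -> non-negative integer count


class FormulaError(ValueError):
    """Raised for malformed formula strings or unknown elements."""


@dataclass(frozen=True)
class Isotope:
    nucleon: int
    mass: float
    abundance: float


class IsotopeTable:
    """Immutable per-element isotope catalogue.

    Parameters
    ----------
    elements:
        Mapping of element symbol to an iterable of :class:`Isotope` (or
        (nucleon, mass, abundance) tuples).  Isotopes are stored sorted by
        nucleon number and validated: positive masses, abundances in [0, 1]
        summing to 1 within 1e-9 per element.
    """

    def __init__(self, elements: Mapping[str, Iterable]):
        table: dict[str, tuple[Isotope, ...]] = {}
        for symbol, isotopes in elements.items():
            isos = tuple(
                sorted(
                    (iso if isinstance(iso, Isotope) else Isotope(*iso) for iso in isotopes),
                    key=lambda i: i.nucleon,
                )
            )
            if not isos:
                raise ValueError(f"element {symbol} has no isotopes")
            total = 0.0
            for iso in isos:
                if iso.mass <= 0:
                    raise ValueError(f"{symbol}-{iso.nucleon}: non-positive mass")
                if not 0.0 <= iso.abundance <= 1.0:
                    raise ValueError(f"{symbol}-{iso.nucleon}: abundance outside [0, 1]")
                total += iso.abundance
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"element {symbol}: abundances sum to {total!r}, not 1")
            table[symbol] = isos
        self._elements = table

    def __getitem__(self, symbol: str) -> tuple[Isotope, ...]:
        try:
            return self._elements[symbol]
        except KeyError:
            raise KeyError(f"element {symbol} not in isotope table") from None

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._elements

    def __iter__(self):
        return iter(self._elements)

    def elements(self) -> tuple[str, ...]:
        return tuple(self._elements)

    def lightest(self, symbol: str) -> Isotope:
        return self[symbol][0]

    def __eq__(self, other) -> bool:
        return isinstance(other, IsotopeTable) and self._key() == other._key()

    def __hash__(self) -> int:
        return hash(self._key())

    def _key(self):
        return tuple(
            (el, tuple((i.nucleon, i.mass, i.abundance) for i in isos))
            for el, isos in sorted(self._elements.items())
        )

    def enrich(self, *specs: "EnrichmentSpec") -> "IsotopeTable":
        """Return a copy with each spec applied via :func:`apply_enrichment`."""
        table = self
        for spec in specs:
            table = apply_enrichment(table, spec)
        return table


@dataclass(frozen=True)
class EnrichmentSpec:
    """Set one heavy isotope of one element to a fixed atom fraction."""

    element: str
    heavy_nucleon: int
    atom_fraction: float


@dataclass(frozen=True)
class IonSpec:
    """Charging convention: protonation (positive) or deprotonation (negative)."""

    charge: int = 1
    polarity: str = "positive"  # or "negative"
    adduct: str = "protonation"  # or "deprotonation"

    def __post_init__(self):
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.adduct not in ("protonation", "deprotonation"):
            raise ValueError(f"unknown adduct {self.adduct!r}")
        if self.polarity == "negative" and self.adduct != "deprotonation":
            raise ValueError("negative polarity requires deprotonation")
        if self.polarity == "positive" and self.adduct != "protonation":
            raise ValueError("positive polarity requires protonation")


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def _load_tsv(name: str) -> list[list[str]]:
    text = resources.files("sipsim.data").joinpath(name).read_text()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


_NATURAL: IsotopeTable | None = None


def natural_table() -> IsotopeTable:
    """The shipped natural-abundance isotope table (C, H, O, N, S, P)."""
    global _NATURAL
    if _NATURAL is None:
        elements: dict[str, list[Isotope]] = {}
        for symbol, nucleon, mass, abundance in _load_tsv("isotopes.tsv"):
            elements.setdefault(symbol, []).append(
                Isotope(int(nucleon), float(mass), float(abundance))
            )
        _NATURAL = IsotopeTable(elements)
    return _NATURAL


def parse_formula(text: str, table: IsotopeTable | None = None) -> Formula:
    """Parse ``"C6H12O6"``-style formula strings into an element->count map.

    Counts default to 1; a repeated element accumulates.  Unknown element
    symbols (checked against *table*, default the shipped natural table) and
    zero counts are errors.
    """
    if table is None:
        table = natural_table()
    if not text:
        raise FormulaError("empty formula string")
    formula: Formula = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or not m.group(1):
            raise FormulaError(f"cannot parse formula at {text[pos:]!r}")
        symbol, digits = m.group(1), m.group(2)
        if symbol not in table:
            raise FormulaError(f"unknown element {symbol}")
        count = int(digits) if digits else 1
        if count <= 0:
            raise FormulaError(f"zero count for element {symbol}")
        formula[symbol] = formula.get(symbol, 0) + count
        pos = m.end()
    return formula


def formula_to_string(f: Formula) -> str:
    """Hill-ish rendering: C, H first, then the rest alphabetically."""
    order = [el for el in ("C", "H") if el in f]
    order += sorted(el for el in f if el not in ("C", "H"))
    return "".join(f"{el}{f[el]}" if f[el] != 1 else el for el in order if f[el] > 0)


_ENRICH = re.compile(r"^([A-Z][a-z]?)(\d+)=([0-9.eE+-]+)$")


def parse_enrichment(text: str) -> EnrichmentSpec:
    """Parse CLI-style enrichment specs like ``"C13=0.5"``."""
    m = _ENRICH.match(text.strip())
    if not m:
        raise ValueError(f"cannot parse enrichment spec {text!r} (expected e.g. C13=0.5)")
    return EnrichmentSpec(m.group(1), int(m.group(2)), float(m.group(3)))


def apply_enrichment(table: IsotopeTable, spec: EnrichmentSpec) -> IsotopeTable:
    """Return a new table with one heavy isotope forced to ``atom_fraction``.

    The remaining isotopes of that element are rescaled proportionally to
    their prior ratios so the element still sums to 1.  The input table is
    not mutated.
    """
    if not 0.0 <= spec.atom_fraction <= 1.0:
        raise ValueError(f"atom_fraction {spec.atom_fraction} outside [0, 1]")
    isotopes = table[spec.element]
    if spec.heavy_nucleon not in {i.nucleon for i in isotopes}:
        raise ValueError(
            f"{spec.element}-{spec.heavy_nucleon} is not a listed isotope of {spec.element}"
        )
    others_total = sum(i.abundance for i in isotopes if i.nucleon != spec.heavy_nucleon)
    new_isos = []
    for iso in isotopes:
        if iso.nucleon == spec.heavy_nucleon:
            ab = spec.atom_fraction
        elif others_total > 0.0:
            ab = iso.abundance / others_total * (1.0 - spec.atom_fraction)
        else:
            # Degenerate prior (heavy isotope already at 1): split the
            # remainder evenly among the other isotopes.
            ab = (1.0 - spec.atom_fraction) / (len(isotopes) - 1)
        new_isos.append(Isotope(iso.nucleon, iso.mass, ab))
    elements = {el: table[el] for el in table}
    elements[spec.element] = new_isos
    return IsotopeTable(elements)


def monoisotopic_mass(f: Formula, table: IsotopeTable) -> float:
    """All-lightest-isotope mass in Da (the envelope anchor).

    The anchor is defined by composition, not probability, so it is stable
    across enrichment levels even when a heavy isotope dominates.
    """
    if not f or all(c == 0 for c in f.values()):
        raise FormulaError("empty formula")
    return sum(count * table.lightest(el).mass for el, count in f.items())


def expected_mass(f: Formula, table: IsotopeTable) -> float:
    """Probability-weighted mean mass of the full isotopologue distribution."""
    if not f:
        raise FormulaError("empty formula")
    return sum(
        count * sum(i.abundance * i.mass for i in table[el]) for el, count in f.items()
    )


def mz_from_neutral(neutral_mass: float, ion: IonSpec) -> float:
    """m/z of [M + zH]z+ or [M − zH]z− using the proton mass."""
    z = ion.charge
    if ion.adduct == "protonation":
        mz = (neutral_mass + z * PROTON_MASS) / z
    else:
        mz = (neutral_mass - z * PROTON_MASS) / z
    if mz <= 0:
        raise ValueError(f"non-positive m/z {mz} for neutral mass {neutral_mass}")
    return mz


def neutral_from_mz(mz: float, ion: IonSpec) -> float:
    """Inverse of :func:`mz_from_neutral`."""
    z = ion.charge
    if ion.adduct == "protonation":
        return mz * z - z * PROTON_MASS
    return mz * z + z * PROTON_MASS
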