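"""Peptide precursor and b/y fragment isotopic envelopes by residue convolution.

A peptide's aggregate envelope is the convolution of the envelopes of its
monomeric units: the distribution of total extra neutrons is the sum of
independent per-residue contributions.  Fragment series exploit this
incrementally — the envelope of b_i is b_{i-1}'s envelope convolved with one
more residue — so all n-1 prefix (b) envelopes cost n-1 convolutions, not a
quadratic rebuild.

Neutral fragment conventions (b/y complementarity is exact by construction):

* b_i  = sum of residues 1..i (the proton appears only at charging)
* y_j  = sum of the last j residues + H2O
* b_i + y_{n-i} = full neutral peptide, element by element
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .chem import Formula, IonSpec, IsotopeTable, monoisotopic_mass
from .envelope import NEUTRON_SPACING, AggregateEnvelope, envelope_fft, envelope_to_sticks
from .spectrum import StickSpectrum

__all__ = [
    "Peptide",
    "Fragment",
    "FragmentSet",
    "residue_formula",
    "peptide_formula",
    "convolve",
    "residue_envelope",
    "precursor_aggregate",
    "precursor_envelope",
    "fragment_envelopes",
]

WATER: Formula = {"H": 2, "O": 1}


@lru_cache(maxsize=1)
def _residue_table() -> dict[str, Formula]:
    from .chem import _load_tsv, parse_formula

    return {code: parse_formula(formula) for code, formula in _load_tsv("residues.tsv")}


def residue_formula(code: str) -> Formula:
    """Dehydrated elemental composition of one canonical residue."""
    try:
        return dict(_residue_table()[code])
    except KeyError:
        raise KeyError(f"unknown residue code {code!r}") from None


@dataclass(frozen=True)
class Peptide:
    """A peptide sequence with explicit terminal groups (default H– and –OH)."""

    sequence: str
    n_term: tuple = (("H", 1),)
    c_term: tuple = (("H", 1), ("O", 1))

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        table = _residue_table()
        for code in self.sequence:
            if code not in table:
                raise KeyError(f"unknown residue code {code!r} in {self.sequence!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def terminal_formula(self) -> Formula:
        out: Formula = {}
        for el, n in list(self.n_term) + list(self.c_term):
            out[el] = out.get(el, 0) + n
        return out


def _add(a: Formula, b: Formula) -> Formula:
    out = dict(a)
    for el, n in b.items():
        out[el] = out.get(el, 0) + n
    return out


def peptide_formula(p: Peptide) -> Formula:
    """Neutral elemental composition: residues plus terminal groups."""
    out: Formula = p.terminal_formula
    for code in p.sequence:
        out = _add(out, residue_formula(code))
    return out


def convolve(a: np.ndarray, b: np.ndarray, counter: list | None = None) -> np.ndarray:
    """Discrete convolution of two probability vectors.

    Length is len(a)+len(b)-1 and the sum is the product of the input sums.
    *counter*, if given, is a single-element list incremented per call — used
    to assert the incremental fragment build stays linear in peptide length.
    """
    if counter is not None:
        counter[0] += 1
    return np.convolve(np.asarray(a, float), np.asarray(b, float))


@lru_cache(maxsize=4096)
def _residue_envelope_cached(code: str, table: IsotopeTable) -> tuple:
    env = envelope_fft(residue_formula(code), table)
    return tuple(env.probabilities)


def residue_envelope(code: str, table: IsotopeTable) -> np.ndarray:
    """Aggregate neutron-count distribution of one residue (cached per table)."""
    return np.array(_residue_envelope_cached(code, table))


@lru_cache(maxsize=64)
def _formula_envelope_cached(items: tuple, table: IsotopeTable) -> tuple:
    return tuple(envelope_fft(dict(items), table).probabilities)


def _terminal_envelope(p: Peptide, table: IsotopeTable) -> np.ndarray:
    items = tuple(sorted(p.terminal_formula.items()))
    return np.array(_formula_envelope_cached(items, table))


def precursor_aggregate(
    p: Peptide, table: IsotopeTable, spacing: float = NEUTRON_SPACING
) -> AggregateEnvelope:
    """Neutral-peptide envelope by left-to-right residue convolution."""
    probs = np.array([1.0])
    for code in p.sequence:
        probs = convolve(probs, residue_envelope(code, table))
    probs = convolve(probs, _terminal_envelope(p, table))
    return AggregateEnvelope(
        anchor_mass=monoisotopic_mass(peptide_formula(p), table),
        spacing=spacing,
        probabilities=probs,
        formula=peptide_formula(p),
    )


def precursor_envelope(
    p: Peptide,
    table: IsotopeTable,
    ion: IonSpec = IonSpec(charge=1),
    spacing: float = NEUTRON_SPACING,
) -> StickSpectrum:
    """Charged precursor stick spectrum (max relative intensity 100)."""
    env = precursor_aggregate(p, table, spacing=spacing)
    return envelope_to_sticks(env, ion, label=f"precursor+{ion.charge}")


@dataclass
class Fragment:
    series: str  # "b" or "y"
    index: int  # 1..n-1
    charge: int
    neutral_formula: Formula
    envelope: AggregateEnvelope
    sticks: StickSpectrum

    @property
    def label(self) -> str:
        return f"{self.series}{self.index}+{self.charge}"


@dataclass
class FragmentSet:
    peptide: Peptide
    fragments: list[Fragment]
    n_convolutions: int = 0
    metadata: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.fragments)

    def __len__(self) -> int:
        return len(self.fragments)

    def get(self, series: str, index: int, charge: int) -> Fragment:
        for frag in self.fragments:
            if (frag.series, frag.index, frag.charge) == (series, index, charge):
                return frag
        raise KeyError(f"no fragment {series}{index}+{charge}")


def fragment_envelopes(
    p: Peptide,
    table: IsotopeTable,
    charges: tuple[int, ...] = (1, 2),
    spacing: float = NEUTRON_SPACING,
) -> FragmentSet:
    """Envelopes for every b_i and y_j (i, j = 1..n-1) at the given charges.

    Prefix (b) and suffix (y) envelopes are built incrementally, n-1
    convolutions per series; charging each envelope at several charge states
    reuses the same neutral distribution.
    """
    for z in charges:
        if z < 1:
            raise ValueError("fragment charge must be >= 1")
    n = len(p)
    counter = [0]
    water_env = np.array(_formula_envelope_cached(tuple(sorted(WATER.items())), table))

    fragments: list[Fragment] = []

    def emit(series: str, index: int, formula: Formula, probs: np.ndarray):
        env = AggregateEnvelope(
            anchor_mass=monoisotopic_mass(formula, table),
            spacing=spacing,
            probabilities=probs,
            formula=formula,
        )
        for z in charges:
            ion = IonSpec(charge=z)
            fragments.append(
                Fragment(
                    series=series,
                    index=index,
                    charge=z,
                    neutral_formula=dict(formula),
                    envelope=env,
                    sticks=envelope_to_sticks(env, ion, label=f"{series}{index}+{z}"),
                )
            )

    # b series: b_0 = delta, b_i = b_{i-1} (*) residue_i
    probs = np.array([1.0])
    formula: Formula = {}
    for i in range(1, n):
        probs = convolve(probs, residue_envelope(p.sequence[i - 1], table), counter)
        formula = _add(formula, residue_formula(p.sequence[i - 1]))
        emit("b", i, formula, probs)
    b_convolutions = counter[0]

    # y series: y_0 = H2O envelope, y_j = y_{j-1} (*) residue_{n-j+1}
    probs = water_env
    formula = dict(WATER)
    for j in range(1, n):
        probs = convolve(probs, residue_envelope(p.sequence[n - j], table), counter)
        formula = _add(formula, residue_formula(p.sequence[n - j]))
        emit("y", j, formula, probs)

    fragments.sort(key=lambda fr: (fr.series, fr.index, fr.charge))
    return FragmentSet(
        peptide=p,
        fragments=fragments,
        n_convolutions=counter[0],
        metadata={"b_convolutions": b_convolutions, "charges": tuple(charges)},
    )
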