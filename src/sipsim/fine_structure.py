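"""Isotopic fine structures: individual isotopologue species with exact masses.

A fine structure resolves what the aggregate envelope lumps together: two
isotopologues with the same extra-neutron count but different composition
(say one 13C versus one 15N) have slightly different exact masses, and high
resolution FTMS can separate them.  Species are therefore keyed on the full
per-element isotope composition, never on mass.

Two generators are provided: a Monte Carlo sampler that draws per-element
multinomial isotope counts (scales to any formula, captures low-abundance
variants given enough draws) and an exact enumerator used as its oracle for
formulas whose composition space is small enough to list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .chem import EnrichmentSpec, Formula, FormulaError, IsotopeTable, monoisotopic_mass
from .envelope import NEUTRON_SPACING, AggregateEnvelope

__all__ = [
    "Species",
    "FineSpectrum",
    "simulate_fine_structure",
    "exact_fine_structure",
    "aggregate_by_nucleon",
    "jitter_overlapping_peaks",
    "composition_string",
    "fine_structure_table",
]

# Composition = tuple of (element, counts-per-isotope tuple), elements sorted
# alphabetically, isotope slots in ascending nucleon order (the table order).
Composition = tuple


@dataclass(frozen=True)
class Species:
    composition: Composition
    mass: float
    probability: float


@dataclass
class FineSpectrum:
    """Isotopologue species of one formula, sorted by ascending mass."""

    species: list[Species]
    formula: Formula
    table: IsotopeTable
    n_draws: int | None = None
    seed: int | None = None
    prune_threshold: float = 0.0
    enrichment: tuple[EnrichmentSpec, ...] = ()
    display_mass: np.ndarray | None = None  # set by jitter_overlapping_peaks

    def __len__(self) -> int:
        return len(self.species)

    @property
    def masses(self) -> np.ndarray:
        return np.array([s.mass for s in self.species])

    @property
    def probabilities(self) -> np.ndarray:
        return np.array([s.probability for s in self.species])

    def total_probability(self) -> float:
        return float(sum(s.probability for s in self.species))


def _composition_mass(comp: Composition, table: IsotopeTable) -> float:
    return sum(
        n * iso.mass
        for el, counts in comp
        for n, iso in zip(counts, table[el])
    )


def composition_string(comp: Composition, table: IsotopeTable) -> str:
    """Heavy-isotope annotation, e.g. ``"13C2 18O1"``; all-light gives ``""``."""
    parts = []
    for el, counts in comp:
        for n, iso in zip(counts[1:], table[el][1:]):
            if n > 0:
                parts.append(f"{iso.nucleon}{el}{n}")
    return " ".join(parts)


def _finalize(raw: dict[Composition, float], table: IsotopeTable, prune: float) -> list[Species]:
    species = [
        Species(comp, _composition_mass(comp, table), p)
        for comp, p in raw.items()
        if p >= prune and p > 0.0
    ]
    species.sort(key=lambda s: (s.mass, s.composition))
    return species


def simulate_fine_structure(
    f: Formula,
    table: IsotopeTable,
    n_draws: int = 1_000_000,
    seed: int | None = None,
    prune_threshold: float = 1e-8,
) -> FineSpectrum:
    """Monte Carlo fine structure via per-element multinomial draws.

    Each draw samples, for every element independently, an isotope-count
    vector from multinomial(count, abundances); identical compositions are
    tallied and probabilities estimated as tally / n_draws.  Deterministic
    given *seed* (required for reproducible output; ``None`` is allowed but
    not reproducible).
    """
    if not f or all(c == 0 for c in f.values()):
        raise FormulaError("empty formula")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if not 0.0 <= prune_threshold < 1.0:
        raise ValueError("prune_threshold must be in [0, 1)")
    rng = np.random.default_rng(seed)
    elements = sorted(el for el, c in f.items() if c > 0)
    blocks = []
    for el in elements:
        pvals = np.array([iso.abundance for iso in table[el]])
        blocks.append(rng.multinomial(f[el], pvals, size=n_draws))
    draws = np.hstack(blocks)  # (n_draws, total isotope slots)
    uniq, counts = np.unique(draws, axis=0, return_counts=True)
    widths = [len(table[el]) for el in elements]
    offsets = np.cumsum([0] + widths)
    raw: dict[Composition, float] = {}
    for row, tally in zip(uniq, counts):
        comp = tuple(
            (el, tuple(int(x) for x in row[offsets[i] : offsets[i + 1]]))
            for i, el in enumerate(elements)
        )
        raw[comp] = tally / n_draws
    species = _finalize(raw, table, prune_threshold)
    return FineSpectrum(
        species=species,
        formula=dict(f),
        table=table,
        n_draws=n_draws,
        seed=seed,
        prune_threshold=prune_threshold,
    )


def _element_compositions(n: int, pvals: list[float]) -> list[tuple[tuple[int, ...], float]]:
    """All ways to split n atoms over the isotopes, with multinomial probability."""
    k = len(pvals)
    out: list[tuple[tuple[int, ...], float]] = []

    def rec(slot: int, remaining: int, counts: list[int]):
        if slot == k - 1:
            counts.append(remaining)
            coeff = math.factorial(n)
            p = 1.0
            for c, pv in zip(counts, pvals):
                coeff //= math.factorial(c)
                p *= pv**c
            out.append((tuple(counts), coeff * p))
            counts.pop()
            return
        for c in range(remaining + 1):
            counts.append(c)
            rec(slot + 1, remaining - c, counts)
            counts.pop()

    rec(0, n, [])
    return out


def exact_fine_structure(
    f: Formula,
    table: IsotopeTable,
    prune_threshold: float = 0.0,
    cap: int = 1_000_000,
) -> FineSpectrum:
    """Brute-force enumeration of every isotopologue with exact probability.

    Probabilities over all species sum to 1 (to floating-point accuracy)
    before pruning.  Raises if the composition space exceeds *cap*.
    """
    if not f or all(c == 0 for c in f.values()):
        raise FormulaError("empty formula")
    elements = sorted(el for el, c in f.items() if c > 0)
    size = 1
    for el in elements:
        size *= math.comb(f[el] + len(table[el]) - 1, len(table[el]) - 1)
        if size > cap:
            raise ValueError(
                f"{size}+ isotopologue compositions exceed the enumeration cap {cap}"
            )
    per_element = [
        _element_compositions(f[el], [iso.abundance for iso in table[el]]) for el in elements
    ]
    raw: dict[Composition, float] = {}
    for combo in product(*per_element):
        p = 1.0
        for _, pe in combo:
            p *= pe
        comp = tuple((el, counts) for el, (counts, _) in zip(elements, combo))
        raw[comp] = p
    species = _finalize(raw, table, prune_threshold)
    return FineSpectrum(
        species=species,
        formula=dict(f),
        table=table,
        prune_threshold=prune_threshold,
    )


def aggregate_by_nucleon(
    fs: FineSpectrum, spacing: float = NEUTRON_SPACING
) -> AggregateEnvelope:
    """Regroup species by total extra-neutron count; conserves probability."""
    table = fs.table
    ks = []
    for s in fs.species:
        k = 0
        for el, counts in s.composition:
            base = table[el][0].nucleon
            k += sum(n * (iso.nucleon - base) for n, iso in zip(counts, table[el]))
        ks.append(k)
    kmax = max(ks) if ks else 0
    probs = np.zeros(kmax + 1)
    for k, s in zip(ks, fs.species):
        probs[k] += s.probability
    return AggregateEnvelope(
        anchor_mass=monoisotopic_mass(fs.formula, table),
        spacing=spacing,
        probabilities=probs,
        formula=dict(fs.formula),
    )


def jitter_overlapping_peaks(fs: FineSpectrum, min_separation: float = 0.03) -> FineSpectrum:
    """Displace near-coincident peaks for display only.

    Peaks closer than *min_separation* are spread symmetrically about their
    cluster's mean true mass so every displayed gap is >= *min_separation*
    and the mass rank order is preserved.  True masses are untouched; the
    displayed positions land in ``display_mass``.
    """
    masses = fs.masses
    if masses.size <= 1:
        out = FineSpectrum(**{**fs.__dict__})
        out.display_mass = masses.copy()
        return out
    s = min_separation
    # Greedy 1D anti-overlap: clusters of (member original masses); merge
    # while adjacent clusters' spread positions would still collide.
    clusters: list[list[float]] = []
    for m in masses:
        clusters.append([m])
        while len(clusters) > 1:
            prev, last = clusters[-2], clusters[-1]
            prev_end = float(np.mean(prev)) + (len(prev) - 1) / 2 * s
            last_start = float(np.mean(last)) - (len(last) - 1) / 2 * s
            if last_start - prev_end < s - 1e-12:
                merged = prev + last
                clusters[-2:] = [merged]
            else:
                break
    display = []
    for cluster in clusters:
        center = float(np.mean(cluster))
        start = center - (len(cluster) - 1) / 2 * s
        display.extend(start + i * s for i in range(len(cluster)))
    out = FineSpectrum(**{**fs.__dict__})
    out.display_mass = np.array(display)
    return out


def fine_structure_table(fs: FineSpectrum):
    """Export as a DataFrame with mass, probability, and composition columns."""
    import pandas as pd

    return pd.DataFrame(
        {
            "mass": fs.masses,
            "probability": fs.probabilities,
            "composition": [composition_string(s.composition, fs.table) for s in fs.species],
        }
    )
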