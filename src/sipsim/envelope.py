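"""Aggregate isotopic envelopes by elemental FFT convolution.

The aggregate envelope of a molecule ignores isotopic fine structure: it is
the probability distribution of the total number of *extra neutrons* k
(relative to the all-lightest composition).  Each element contributes the
count-fold convolution power of its single-atom neutron distribution, and
the molecular envelope is the convolution of the elemental ones.  All of
this is done in Fourier space: transform each single-atom distribution,
raise pointwise to the stoichiometric count, multiply across elements, and
invert once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .chem import Formula, FormulaError, IonSpec, IsotopeTable, monoisotopic_mass, mz_from_neutral
from .spectrum import StickSpectrum

__all__ = [
    "NEUTRON_SPACING",
    "AggregateEnvelope",
    "atom_neutron_distribution",
    "elemental_distribution",
    "envelope_fft",
    "envelope_to_sticks",
]

#: Default mass per extra neutron: the 13C − 12C mass difference in Da.
#: CHNOPS envelopes are carbon-dominated, so aggregate peaks are placed at
#: 13C spacing by default; pass ``spacing=`` to override.
NEUTRON_SPACING = 1.003355

_CLAMP = 1e-12  # kill inverse-FFT ringing below this magnitude
_TRIM = 1e-10  # trailing probabilities below this are trimmed


@dataclass
class AggregateEnvelope:
    """Probabilities per extra-neutron count, anchored at the monoisotopic mass."""

    anchor_mass: float
    spacing: float
    probabilities: np.ndarray
    formula: Formula | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.probabilities = np.asarray(self.probabilities, dtype=float)

    def __len__(self) -> int:
        return self.probabilities.size

    @property
    def masses(self) -> np.ndarray:
        return self.anchor_mass + self.spacing * np.arange(self.probabilities.size)

    def mean_k(self) -> float:
        """Mean extra-neutron count (linear in atom-fraction enrichment)."""
        p = self.probabilities
        return float(np.arange(p.size) @ p / p.sum())


def atom_neutron_distribution(element: str, table: IsotopeTable) -> np.ndarray:
    """Single-atom probability vector over k = nucleon − lightest nucleon.

    Elements with non-contiguous isotopes (e.g. S with A = 32, 33, 34, 36)
    produce zeros at the missing k values.
    """
    isotopes = table[element]
    base = isotopes[0].nucleon
    dist = np.zeros(isotopes[-1].nucleon - base + 1)
    for iso in isotopes:
        dist[iso.nucleon - base] = iso.abundance
    return dist


def elemental_distribution(
    element: str, count: int, table: IsotopeTable, length: int | None = None
) -> np.ndarray:
    """Neutron-count distribution of *count* atoms of one element.

    The single-atom distribution is raised to its count-th convolution power
    via FFT -> pointwise power -> inverse FFT.  ``count == 0`` yields the
    convolution identity (a delta at k = 0).
    """
    if count < 0:
        raise ValueError("count must be non-negative")
    atom = atom_neutron_distribution(element, table)
    max_k = (atom.size - 1) * count
    if length is None:
        length = _fft_length(max_k)
    elif length < max_k + 1:
        raise ValueError(f"grid length {length} cannot hold k up to {max_k}")
    if count == 0:
        out = np.zeros(length)
        out[0] = 1.0
        return out
    spec = np.fft.rfft(atom, n=length) ** count
    dist = np.fft.irfft(spec, n=length)
    dist[np.abs(dist) < _CLAMP] = 0.0
    np.clip(dist, 0.0, None, out=dist)
    return dist


def _fft_length(max_k: int) -> int:
    return 1 << int(np.ceil(np.log2(max(max_k + 1, 2))))


def envelope_fft(
    f: Formula,
    table: IsotopeTable,
    max_k: int | None = None,
    spacing: float = NEUTRON_SPACING,
    trim: float = _TRIM,
) -> AggregateEnvelope:
    """Aggregate envelope of a formula by elemental FFT convolution.

    One inverse FFT of the pointwise product of all elemental transforms.
    The grid is the smallest power of two holding the maximal reachable k
    (or ``max_k`` if given — truncation then emits a warning quantifying the
    lost probability).  Trailing probabilities below *trim* are dropped.
    """
    if not f or all(c == 0 for c in f.values()):
        raise FormulaError("empty formula")
    reachable = sum(
        (atom_neutron_distribution(el, table).size - 1) * count for el, count in f.items()
    )
    # Always compute on the full reachable grid (power of two, so the FFT
    # convolution is linear, never circular); truncate afterwards if asked.
    length = _fft_length(reachable)
    spec = np.ones(length // 2 + 1, dtype=complex)
    for el, count in f.items():
        if count == 0:
            continue
        atom = atom_neutron_distribution(el, table)
        spec *= np.fft.rfft(atom, n=length) ** count
    probs = np.fft.irfft(spec, n=length)
    probs[np.abs(probs) < _CLAMP] = 0.0
    np.clip(probs, 0.0, None, out=probs)
    k_cap = reachable if max_k is None else min(max_k, reachable)
    if k_cap < reachable:
        lost = float(probs[k_cap + 1 :].sum())
        warnings.warn(
            f"envelope truncated at k={k_cap} (reachable {reachable}); "
            f"{lost:.3g} probability dropped",
            stacklevel=2,
        )
    probs = probs[: k_cap + 1]
    keep = probs.size
    while keep > 1 and probs[keep - 1] < trim:
        keep -= 1
    probs = probs[:keep]
    return AggregateEnvelope(
        anchor_mass=monoisotopic_mass(f, table),
        spacing=spacing,
        probabilities=probs,
        formula=dict(f),
    )


def envelope_to_sticks(env: AggregateEnvelope, ion: IonSpec, label: str = "") -> StickSpectrum:
    """Charge an envelope into an m/z stick spectrum, max intensity 100."""
    mz = np.array([mz_from_neutral(m, ion) for m in env.masses])
    intensity = env.probabilities.copy()
    peak = intensity.max()
    if peak > 0:
        intensity = intensity * (100.0 / peak)
    return StickSpectrum(mz=mz, intensity=intensity, label=label)
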