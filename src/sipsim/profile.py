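"""Score-vs-enrichment profiles and atom-% enrichment point estimation.

The estimator regenerates the theoretical precursor (and, by default, b/y
fragment) spectra of a peptide on a grid of atom fractions, scores each
against the observed scan, and reads off the argmax.  The full width at
half maximum (FWHM) of the min-max-normalized profile is the resolution
diagnostic: a scorer with a narrower peak discriminates enrichment levels
more sharply.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem import EnrichmentSpec, IonSpec, IsotopeTable
from .peptides import Peptide, fragment_envelopes, precursor_envelope
from .scoring import (
    DEFAULT_TOLERANCE,
    entropy_similarity,
    score_mvh,
    score_wdp,
    score_xcorr,
)
from .spectrum import Spectrum, StickSpectrum

__all__ = [
    "ScoreProfile",
    "default_grid",
    "theoretical_library",
    "score_spectrum",
    "score_profile",
    "estimate_enrichment",
    "profile_fwhm",
]

SCORER_NAMES = ("wdp", "xcorr", "mvh", "entropy")


def default_grid(step: float = 0.01) -> np.ndarray:
    """Atom-fraction grid spanning 0–100% enrichment."""
    return np.round(np.arange(0.0, 1.0 + step / 2, step), 10)


@dataclass
class ScoreProfile:
    grid: np.ndarray
    scores: dict[str, np.ndarray]
    peptide: Peptide | None = None
    element: str = "C"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        for name, vec in self.scores.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != self.grid.shape:
                raise ValueError(f"score vector {name!r} does not align with grid")
            self.scores[name] = vec


def theoretical_library(
    p: Peptide,
    table: IsotopeTable,
    element: str = "C",
    heavy_nucleon: int = 13,
    grid: np.ndarray | None = None,
    precursor_charge: int = 2,
    fragment_charges: tuple[int, ...] = (1, 2),
    include_fragments: bool = True,
) -> list[tuple[float, list[StickSpectrum]]]:
    """Theoretical envelope sets for every grid point.

    The library depends only on the peptide and the grid, not on any
    observed scan, so it can be built once and scored against many spectra.
    """
    if grid is None:
        grid = default_grid()
    library = []
    for fraction in np.asarray(grid, dtype=float):
        enriched = table.enrich(EnrichmentSpec(element, heavy_nucleon, float(fraction)))
        envelopes = [precursor_envelope(p, enriched, IonSpec(charge=precursor_charge))]
        if include_fragments:
            frags = fragment_envelopes(p, enriched, charges=fragment_charges)
            envelopes.extend(fr.sticks for fr in frags)
        library.append((float(fraction), envelopes))
    return library


def score_spectrum(
    envelopes: list[StickSpectrum],
    s: Spectrum,
    scorers=SCORER_NAMES,
    tolerance: float = DEFAULT_TOLERANCE,
) -> dict[str, float]:
    """Score one theoretical envelope set against one observed scan."""
    out: dict[str, float] = {}
    if "wdp" in scorers:
        out["wdp"] = score_wdp(envelopes, s, tolerance=tolerance)
    if "xcorr" in scorers:
        out["xcorr"] = score_xcorr(envelopes, s)
    if "mvh" in scorers:
        out["mvh"] = score_mvh(envelopes, s, tolerance=tolerance)
    if "entropy" in scorers:
        combined = StickSpectrum(
            mz=np.concatenate([e.mz for e in envelopes]),
            intensity=np.concatenate([e.intensity for e in envelopes]),
        )
        out["entropy"] = entropy_similarity(combined, s, tolerance=tolerance)
    return out


def score_profile(
    p: Peptide,
    s: Spectrum,
    table: IsotopeTable,
    element: str = "C",
    heavy_nucleon: int = 13,
    grid: np.ndarray | None = None,
    scorers=SCORER_NAMES,
    tolerance: float = DEFAULT_TOLERANCE,
    precursor_charge: int = 2,
    fragment_charges: tuple[int, ...] = (1, 2),
    include_fragments: bool = True,
    library: list | None = None,
) -> ScoreProfile:
    """Score-vs-enrichment curves for the requested scoring functions.

    Deterministic: same inputs, bit-identical output.  Pass a precomputed
    *library* (from :func:`theoretical_library`) to amortize the theoretical
    spectra across many observed scans.
    """
    if library is None:
        library = theoretical_library(
            p,
            table,
            element=element,
            heavy_nucleon=heavy_nucleon,
            grid=grid,
            precursor_charge=precursor_charge,
            fragment_charges=fragment_charges,
            include_fragments=include_fragments,
        )
    fractions = np.array([fr for fr, _ in library])
    scores: dict[str, list[float]] = {name: [] for name in scorers}
    for _, envelopes in library:
        values = score_spectrum(envelopes, s, scorers=scorers, tolerance=tolerance)
        for name in scorers:
            scores[name].append(values[name])
    return ScoreProfile(
        grid=fractions,
        scores={name: np.array(vals) for name, vals in scores.items()},
        peptide=p,
        element=element,
        metadata={"tolerance": tolerance, "include_fragments": include_fragments},
    )


def profile_fwhm(grid: np.ndarray, scores: np.ndarray) -> float | None:
    """FWHM of the min-max-normalized score curve by linear interpolation.

    Invariant to affine rescaling of the scores.  Returns None for flat
    profiles.  Half-maximum crossings beyond the grid ends clip to the ends.
    """
    scores = np.asarray(scores, dtype=float)
    lo, hi = scores.min(), scores.max()
    if hi - lo <= 0:
        return None
    norm = (scores - lo) / (hi - lo)
    peak = int(np.argmax(norm))
    # walk left from the peak to the 0.5 crossing
    left = grid[0]
    for i in range(peak, 0, -1):
        if norm[i - 1] < 0.5 <= norm[i]:
            frac = (0.5 - norm[i - 1]) / (norm[i] - norm[i - 1])
            left = grid[i - 1] + frac * (grid[i] - grid[i - 1])
            break
    right = grid[-1]
    for i in range(peak, len(norm) - 1):
        if norm[i] >= 0.5 > norm[i + 1]:
            frac = (norm[i] - 0.5) / (norm[i] - norm[i + 1])
            right = grid[i] + frac * (grid[i + 1] - grid[i])
            break
    return float(right - left)


def estimate_enrichment(
    profile: ScoreProfile, function_name: str = "wdp"
) -> tuple[float | None, float | None]:
    """Point estimate (grid argmax, ties to the lowest fraction) and FWHM.

    A flat profile has no defined argmax and returns (None, None).
    """
    scores = profile.scores[function_name]
    if scores.max() - scores.min() <= 0:
        return None, None
    idx = int(np.argmax(scores))  # argmax returns the first (lowest) maximizer
    return float(profile.grid[idx]), profile_fwhm(profile.grid, scores)
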