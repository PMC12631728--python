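"""Spectrum preprocessing, peak matching, and PSM scoring functions.

Four scorers compare theoretical isotopic stick spectra with an observed
centroided scan:

* WDP — weighted dot product: per fragment envelope, sum of theoretical
  relative intensity times the square root of the matched observed
  intensity, normalized by the envelope's self-product, then summed over
  envelopes.  Every stick of every isotopic envelope contributes, which is
  what makes the score sharp as a function of enrichment level.
* XCorr — SEQUEST-style cross correlation: binned dot product minus the
  mean over shifted dot products (background subtraction), with
  square-rooted, regionally normalized observed intensities.
* MVH — MyriMatch-style multivariate hypergeometric: −ln probability of the
  observed pattern of per-intensity-class matches when drawing the
  theoretical sticks' bins at random from the candidate m/z bins.
* Spectral entropy similarity: 1 − (2·S_mix − S_a − S_b)/ln 4 on
  sum-normalized, tolerance-aligned spectra.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .spectrum import Spectrum, StickSpectrum

__all__ = [
    "MatchResult",
    "PSMRecord",
    "denoise",
    "match_peaks",
    "score_wdp",
    "score_xcorr",
    "score_mvh",
    "entropy_similarity",
]

DEFAULT_TOLERANCE = 0.01  # Da, suited to FT MS2 centroids
XCORR_BIN_WIDTH = 1.0005079  # Da, the classic average nucleon spacing bin
XCORR_OFFSET_RANGE = 75  # bins either side for background subtraction


@dataclass
class MatchResult:
    """Greedy theoretical-to-observed assignment within a mass tolerance."""

    pairs: list[tuple[int, int]]  # (theoretical index, observed index)
    mz_errors: list[float]
    unmatched_theoretical: list[int]
    unmatched_observed: list[int]

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


@dataclass
class PSMRecord:
    """A peptide-spectrum match with whatever scores were computed."""

    peptide: object
    charge: int
    spectrum: Spectrum
    enrichment: tuple = ()
    scores: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)


def denoise(s: Spectrum, window: float = 100.0, top_n: int = 10) -> Spectrum:
    """Keep only peaks that rank in the top *top_n* within their local window.

    A peak survives if fewer than *top_n* peaks in the m/z window centred on
    it are strictly more intense.  Deterministic; output remains sorted.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    mz, inten = s.mz, s.intensity
    keep = np.zeros(mz.size, dtype=bool)
    half = window / 2.0
    lo = np.searchsorted(mz, mz - half, side="left")
    hi = np.searchsorted(mz, mz + half, side="right")
    for i in range(mz.size):
        stronger = int(np.count_nonzero(inten[lo[i] : hi[i]] > inten[i]))
        keep[i] = stronger < top_n
    return Spectrum(
        mz=mz[keep],
        intensity=inten[keep],
        scan_number=s.scan_number,
        ms_level=s.ms_level,
        retention_time=s.retention_time,
        precursor_mz=s.precursor_mz,
        precursor_charge=s.precursor_charge,
        isolation_width=s.isolation_width,
        extra=dict(s.extra),
    )


def _tolerance_da(tolerance: float, mz: float, ppm: bool) -> float:
    return tolerance * mz * 1e-6 if ppm else tolerance


def _match_disjoint(
    t_mz: np.ndarray, o_mz: np.ndarray, o_int: np.ndarray, tolerance: float
) -> MatchResult:
    """Vectorized best-peak-in-window matching for non-overlapping windows."""
    lo = np.searchsorted(o_mz, t_mz - tolerance, side="left")
    hi = np.searchsorted(o_mz, t_mz + tolerance, side="right")
    width = hi - lo
    best = np.full(t_mz.size, -1, dtype=int)
    best_int = np.full(t_mz.size, -np.inf)
    best_err = np.full(t_mz.size, np.inf)
    for offset in range(int(width.max(initial=0))):
        has = offset < width
        cand = lo + offset
        ci = np.where(has, o_int[np.minimum(cand, o_mz.size - 1)], -np.inf)
        ce = np.where(has, np.abs(o_mz[np.minimum(cand, o_mz.size - 1)] - t_mz), np.inf)
        take = has & ((ci > best_int) | ((ci == best_int) & (ce < best_err)))
        best[take] = cand[take]
        best_int[take] = ci[take]
        best_err[take] = ce[take]
    matched = best >= 0
    pairs = list(zip(np.nonzero(matched)[0].tolist(), best[matched].tolist()))
    errors = (o_mz[best[matched]] - t_mz[matched]).tolist()
    claimed = np.zeros(o_mz.size, dtype=bool)
    claimed[best[matched]] = True
    return MatchResult(
        pairs=pairs,
        mz_errors=errors,
        unmatched_theoretical=np.nonzero(~matched)[0].tolist(),
        unmatched_observed=np.nonzero(~claimed)[0].tolist(),
    )


def match_peaks(
    theoretical: StickSpectrum,
    observed: Spectrum | StickSpectrum,
    tolerance: float = DEFAULT_TOLERANCE,
    ppm: bool = False,
) -> MatchResult:
    """Greedy assignment in descending theoretical intensity.

    Each theoretical stick claims the most intense not-yet-claimed observed
    peak within tolerance (ties by smallest |Δm/z|); each observed peak is
    used at most once.
    """
    t_mz, t_int = theoretical.mz, theoretical.intensity
    o_mz, o_int = observed.mz, observed.intensity
    # Fast path: when the tolerance windows of the theoretical sticks are
    # pairwise disjoint, no two sticks can compete for one observed peak and
    # the greedy assignment decouples into an independent best-in-window
    # choice per stick, which vectorizes.
    if t_mz.size > 1 and o_mz.size > 0 and not ppm:
        if np.min(np.diff(t_mz)) > 2.0 * tolerance:
            return _match_disjoint(t_mz, o_mz, o_int, tolerance)
    claimed = np.zeros(o_mz.size, dtype=bool)
    pairs: list[tuple[int, int]] = []
    errors: list[float] = []
    order = np.argsort(-t_int, kind="stable")
    for ti in order:
        tol = _tolerance_da(tolerance, t_mz[ti], ppm)
        lo = int(np.searchsorted(o_mz, t_mz[ti] - tol, side="left"))
        hi = int(np.searchsorted(o_mz, t_mz[ti] + tol, side="right"))
        best = -1
        for oi in range(lo, hi):
            if claimed[oi]:
                continue
            if best < 0:
                best = oi
                continue
            if o_int[oi] > o_int[best] or (
                o_int[oi] == o_int[best]
                and abs(o_mz[oi] - t_mz[ti]) < abs(o_mz[best] - t_mz[ti])
            ):
                best = oi
        if best >= 0:
            claimed[best] = True
            pairs.append((int(ti), best))
            errors.append(float(o_mz[best] - t_mz[ti]))
    pairs_sorted = sorted(zip(pairs, errors))
    pairs = [p for p, _ in pairs_sorted]
    errors = [e for _, e in pairs_sorted]
    matched_t = {p[0] for p in pairs}
    return MatchResult(
        pairs=pairs,
        mz_errors=errors,
        unmatched_theoretical=[i for i in range(t_mz.size) if i not in matched_t],
        unmatched_observed=[i for i in range(o_mz.size) if not claimed[i]],
    )


def _as_envelope_list(theoretical) -> list[StickSpectrum]:
    if isinstance(theoretical, StickSpectrum):
        return [theoretical]
    return list(theoretical)


def score_wdp(
    theoretical,
    observed: Spectrum,
    tolerance: float = DEFAULT_TOLERANCE,
    ppm: bool = False,
    sqrt_transform: bool = False,
    normalized: bool = True,
) -> float:
    """Weighted dot product over one or many theoretical envelopes.

    With ``normalized=True`` each envelope contributes the cosine between
    its stick intensities and the matched observed intensities,
    Σ t_i·o_i / (‖t‖·‖o_matched‖), so a perfect (or proportional) match of
    every stick scores exactly 1 per envelope, and by Cauchy–Schwarz the
    noise-free score-vs-enrichment argmax sits exactly at the generating
    level — no width bias.  Linear observed intensities make this a matched
    filter on the envelope shape, which is what gives WDP the sharpest
    enrichment profile; ``sqrt_transform=True`` switches to a
    variance-stabilized variant, and ``normalized=False`` returns the raw
    summed dot product of max-100-normalized observed intensities.
    """
    envelopes = _as_envelope_list(theoretical)
    if observed.mz.size == 0 or not envelopes:
        return 0.0
    peak = observed.intensity.max()
    if peak <= 0:
        return 0.0
    obs = Spectrum(mz=observed.mz, intensity=observed.intensity * (100.0 / peak))
    xform = np.sqrt if sqrt_transform else (lambda x: x)
    total = 0.0
    for env in envelopes:
        match = match_peaks(env, obs, tolerance=tolerance, ppm=ppm)
        if not match.pairs:
            continue
        ti = np.array([p[0] for p in match.pairs])
        oi = np.array([p[1] for p in match.pairs])
        t_vec = env.intensity
        o_vec = xform(obs.intensity[oi])
        dot = float(t_vec[ti] @ o_vec)
        if normalized:
            denom = float(np.linalg.norm(t_vec) * np.linalg.norm(o_vec))
            dot = dot / denom if denom > 0 else 0.0
        total += dot
    return total


def _bin_spectrum(mz: np.ndarray, intensity: np.ndarray, bin_width: float, n_bins: int) -> np.ndarray:
    idx = np.round(mz / bin_width).astype(int)
    ok = (idx >= 0) & (idx < n_bins)
    out = np.zeros(n_bins)
    np.maximum.at(out, idx[ok], intensity[ok])
    return out


def _xcorr_preprocess(observed: Spectrum, n_regions: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """sqrt intensities, then normalize each of n_regions m/z regions to 50."""
    inten = np.sqrt(observed.intensity)
    mz = observed.mz
    if mz.size == 0:
        return mz, inten
    edges = np.linspace(mz[0], mz[-1] + 1e-9, n_regions + 1)
    out = inten.copy()
    for r in range(n_regions):
        sel = (mz >= edges[r]) & (mz < edges[r + 1])
        if np.any(sel):
            peak = out[sel].max()
            if peak > 0:
                out[sel] *= 50.0 / peak
    return mz, out


def score_xcorr(
    theoretical,
    observed: Spectrum,
    bin_width: float = XCORR_BIN_WIDTH,
    offset_range: int = XCORR_OFFSET_RANGE,
    max_mz: float | None = None,
) -> float:
    """SEQUEST-style cross correlation with background subtraction.

    score = dot(obs, theo) − mean over offsets τ ∈ [−offset_range, +offset_range]\\{0}
    of dot(obs, theo shifted by τ bins).  Observed intensities are
    square-rooted and regionally normalized before binning; the result is
    scaled by 1e-4 as in the classic formulation.
    """
    envelopes = _as_envelope_list(theoretical)
    t_mz = np.concatenate([e.mz for e in envelopes]) if envelopes else np.array([])
    t_int = np.concatenate([e.intensity for e in envelopes]) if envelopes else np.array([])
    if t_mz.size == 0 or observed.mz.size == 0:
        return 0.0
    if max_mz is None:
        max_mz = max(float(t_mz.max()), float(observed.mz.max()))
    n_bins = int(np.ceil(max_mz / bin_width)) + offset_range + 2
    o_mz, o_int = _xcorr_preprocess(observed)
    obs = _bin_spectrum(o_mz, o_int, bin_width, n_bins)
    theo = _bin_spectrum(t_mz, t_int, bin_width, n_bins)
    # One correlation pass gives every offset dot product at once.
    corr = np.correlate(obs, theo, mode="full")  # lag τ at index n_bins-1+τ
    center = n_bins - 1
    dot0 = corr[center]
    lags = np.concatenate(
        [corr[center - offset_range : center], corr[center + 1 : center + offset_range + 1]]
    )
    return float((dot0 - lags.mean()) * 1e-4)


def _log_comb(n: int, k: int) -> float:
    if k < 0 or k > n:
        return -math.inf
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def score_mvh(
    theoretical,
    observed: Spectrum,
    n_classes: int = 3,
    tolerance: float = DEFAULT_TOLERANCE,
    ppm: bool = False,
    n_bins: int | None = None,
) -> float:
    """Multivariate hypergeometric score, −ln P of the observed match pattern.

    Observed peaks are split by intensity rank into *n_classes* equal-count
    classes (class 0 = most intense); the candidate m/z range is discretized
    into *n_bins* bins of width 2·tolerance (by default spanning the union
    of theoretical and observed m/z).  Drawing one bin per theoretical stick
    without replacement, P is the multivariate hypergeometric probability of
    the observed per-class match counts; the score is −ln P, so less
    probable (more intensity-concentrated) match patterns score higher.
    """
    envelopes = _as_envelope_list(theoretical)
    t_mz = np.concatenate([e.mz for e in envelopes]) if envelopes else np.array([])
    t_int = np.concatenate([e.intensity for e in envelopes]) if envelopes else np.array([])
    n_sticks = int(t_mz.size)
    if n_sticks == 0 or observed.mz.size == 0:
        return 0.0
    combined = StickSpectrum(mz=t_mz, intensity=t_int)
    match = match_peaks(combined, observed, tolerance=tolerance, ppm=ppm)
    n_obs = observed.mz.size
    if n_bins is None:
        span = max(float(t_mz.max()), float(observed.mz.max())) - min(
            float(t_mz.min()), float(observed.mz.min())
        )
        n_bins = max(int(span / (2.0 * tolerance)), n_sticks + n_obs, 1)
    # Observed peaks -> intensity classes by rank, equal counts.
    order = np.argsort(-observed.intensity, kind="stable")
    classes = np.empty(n_obs, dtype=int)
    splits = np.array_split(np.arange(n_obs), n_classes)
    for c, chunk in enumerate(splits):
        classes[order[chunk]] = c
    class_sizes = np.array([len(chunk) for chunk in splits])
    matched_per_class = np.zeros(n_classes, dtype=int)
    for _, oi in match.pairs:
        matched_per_class[classes[oi]] += 1
    n_matched = int(matched_per_class.sum())
    n_empty_bins = n_bins - int(class_sizes.sum())
    if n_empty_bins < 0:
        raise ValueError("n_bins smaller than the observed peak count")
    log_p = sum(
        _log_comb(int(K), int(k)) for K, k in zip(class_sizes, matched_per_class)
    )
    log_p += _log_comb(n_empty_bins, n_sticks - n_matched)
    log_p -= _log_comb(n_bins, n_sticks)
    if log_p == -math.inf:
        return 0.0
    return float(-log_p)


def _align(a, b, tolerance: float) -> tuple[np.ndarray, np.ndarray]:
    """Merge two peak lists onto a shared support by tolerance clustering."""
    mz = np.concatenate([a.mz, b.mz])
    src = np.concatenate([np.zeros(a.mz.size, int), np.ones(b.mz.size, int)])
    inten = np.concatenate([a.intensity, b.intensity])
    order = np.argsort(mz, kind="stable")
    mz, src, inten = mz[order], src[order], inten[order]
    va: list[float] = []
    vb: list[float] = []
    cluster_start = None
    for i in range(mz.size):
        if cluster_start is None or mz[i] - mz[i - 1] > tolerance:
            va.append(0.0)
            vb.append(0.0)
            cluster_start = mz[i]
        if src[i] == 0:
            va[-1] += inten[i]
        else:
            vb[-1] += inten[i]
    return np.array(va), np.array(vb)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def entropy_similarity(a, b, tolerance: float = DEFAULT_TOLERANCE) -> float:
    """Spectral entropy similarity in [0, 1].

    Spectra are aligned by tolerance, normalized to sum 1; with S_a, S_b the
    Shannon entropies and S_ab the entropy of the half-half mixture,
    similarity = 1 − (2·S_ab − S_a − S_b)/ln 4.  Identical spectra give 1,
    disjoint supports give 0.
    """
    if a.mz.size == 0 or b.mz.size == 0:
        return 0.0
    va, vb = _align(a, b, tolerance)
    sa, sb = va.sum(), vb.sum()
    if sa <= 0 or sb <= 0:
        return 0.0
    va, vb = va / sa, vb / sb
    mix = 0.5 * (va + vb)
    s_ab = _entropy(mix)
    s_a = _entropy(va)
    s_b = _entropy(vb)
    sim = 1.0 - (2.0 * s_ab - s_a - s_b) / math.log(4.0)
    return float(min(1.0, max(0.0, sim)))
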