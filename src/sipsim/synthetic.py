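"""Synthetic observed spectra and LC–MS/MS runs for testing and benchmarking.

The noise model emulates the features of centroided FT MS2 scans that matter
to the scorers: small Gaussian m/z jitter on true peaks, multiplicative
lognormal intensity jitter (lognormal keeps intensities positive), and a
floor of random noise peaks.  It does not emulate chromatographic peak
shapes, co-isolation chimeras, or detector saturation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .chem import EnrichmentSpec, IonSpec, IsotopeTable, natural_table
from .peptides import Peptide, fragment_envelopes, precursor_envelope
from .spectrum import Spectrum, StickSpectrum

__all__ = [
    "NoiseModel",
    "make_observed",
    "make_run",
    "STANDARD_PEPTIDE",
    "standard_noise_model",
    "standard_theoretical",
    "standard_psm_fixture",
]

#: The worked 15-residue peptide used throughout the examples and fixtures.
STANDARD_PEPTIDE = "HYAHVDCPGHADYVK"


@dataclass(frozen=True)
class NoiseModel:
    """Parameters of the synthetic observed-spectrum generator.

    ``noise_scale`` is the mean (exponential) or maximum (uniform) noise
    peak intensity; fixtures typically set it to max(true)/SNR.
    """

    n_noise_peaks: int = 200
    mz_range: tuple[float, float] = (100.0, 2000.0)
    intensity_distribution: str = "exponential"  # or "uniform"
    noise_scale: float = 10.0
    peak_mz_sigma: float = 0.002
    intensity_cv: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.mz_range[0] >= self.mz_range[1]:
            raise ValueError("invalid m/z range")
        if self.peak_mz_sigma < 0 or self.intensity_cv < 0:
            raise ValueError("sigma and cv must be >= 0")
        if self.intensity_distribution not in ("exponential", "uniform"):
            raise ValueError(f"unknown distribution {self.intensity_distribution!r}")


def make_observed(theoretical: StickSpectrum, nm: NoiseModel) -> Spectrum:
    """Jitter true sticks and add noise peaks; deterministic per seed."""
    rng = np.random.default_rng(nm.seed)
    mz = theoretical.mz.copy()
    inten = theoretical.intensity.copy()
    if nm.peak_mz_sigma > 0:
        mz = mz + rng.normal(0.0, nm.peak_mz_sigma, size=mz.size)
    if nm.intensity_cv > 0:
        sigma = np.sqrt(np.log1p(nm.intensity_cv**2))
        inten = inten * rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=inten.size)
    if nm.n_noise_peaks > 0:
        noise_mz = rng.uniform(*nm.mz_range, size=nm.n_noise_peaks)
        if nm.intensity_distribution == "exponential":
            noise_int = rng.exponential(nm.noise_scale, size=nm.n_noise_peaks)
        else:
            noise_int = rng.uniform(0.0, nm.noise_scale, size=nm.n_noise_peaks)
        mz = np.concatenate([mz, noise_mz])
        inten = np.concatenate([inten, noise_int])
    return Spectrum(mz=mz, intensity=inten, ms_level=2)


def make_run(
    n_ms1: int,
    n_ms2_per_ms1: int,
    gradient_minutes: float = 10.0,
    seed: int = 0,
    n_ms1_peaks: int = 50,
) -> list[Spectrum]:
    """Simulate a DDA cycle: each MS1 triggers top-N MS2 scans on its peaks.

    Retention times increase monotonically across the run; every MS2
    precursor m/z is a peak of the preceding MS1 scan.
    """
    rng = np.random.default_rng(seed)
    n_total = n_ms1 * (1 + n_ms2_per_ms1)
    times = np.linspace(0.0, gradient_minutes, n_total, endpoint=False)
    scans: list[Spectrum] = []
    scan_number = 0
    t_idx = 0
    for _ in range(n_ms1):
        scan_number += 1
        mz = np.sort(rng.uniform(300.0, 1500.0, size=n_ms1_peaks))
        inten = rng.exponential(1e6, size=n_ms1_peaks)
        ms1 = Spectrum(
            mz=mz,
            intensity=inten,
            scan_number=scan_number,
            ms_level=1,
            retention_time=float(times[t_idx]),
        )
        scans.append(ms1)
        t_idx += 1
        top = np.argsort(-ms1.intensity)[:n_ms2_per_ms1]
        for j in top:
            scan_number += 1
            frag_mz = np.sort(rng.uniform(100.0, float(ms1.mz[j]) * 2, size=30))
            frag_int = rng.exponential(1e4, size=30)
            scans.append(
                Spectrum(
                    mz=frag_mz,
                    intensity=frag_int,
                    scan_number=scan_number,
                    ms_level=2,
                    retention_time=float(times[t_idx]),
                    precursor_mz=float(ms1.mz[j]),
                    precursor_charge=2,
                    isolation_width=5.0,
                )
            )
            t_idx += 1
    return scans


def standard_noise_model(seed: int, snr: float = 10.0) -> NoiseModel:
    """The standard fixture noise model: 200 noise peaks at the given SNR.

    Theoretical sticks are max-100 normalized, so noise_scale = 100/SNR.
    """
    return NoiseModel(
        n_noise_peaks=200,
        mz_range=(100.0, 2000.0),
        intensity_distribution="exponential",
        noise_scale=100.0 / snr,
        peak_mz_sigma=0.002,
        intensity_cv=0.1,
        seed=seed,
    )


def standard_theoretical(
    enrichment: float,
    table: IsotopeTable | None = None,
    sequence: str = STANDARD_PEPTIDE,
    precursor_charge: int = 2,
    fragment_charges: tuple[int, ...] = (1, 2),
) -> list[StickSpectrum]:
    """Precursor + b/y envelopes of the standard peptide at one 13C level."""
    if table is None:
        table = natural_table()
    enriched = table.enrich(EnrichmentSpec("C", 13, enrichment))
    p = Peptide(sequence)
    envelopes = [precursor_envelope(p, enriched, IonSpec(charge=precursor_charge))]
    envelopes.extend(fr.sticks for fr in fragment_envelopes(p, enriched, fragment_charges))
    return envelopes


def standard_psm_fixture(
    enrichment: float, seed: int, snr: float = 10.0
) -> tuple[Peptide, Spectrum, dict]:
    """A synthetic PSM at a known 13C atom fraction, plus its ground truth."""
    envelopes = standard_theoretical(enrichment)
    combined = StickSpectrum(
        mz=np.concatenate([e.mz for e in envelopes]),
        intensity=np.concatenate([e.intensity for e in envelopes]),
    )
    nm = standard_noise_model(seed, snr=snr)
    observed = make_observed(combined, nm)
    truth = {
        "sequence": STANDARD_PEPTIDE,
        "enrichment": enrichment,
        "seed": seed,
        "snr": snr,
        "noise_model": nm,
    }
    return Peptide(STANDARD_PEPTIDE), observed, truth
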