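"""In-memory containers for centroided spectra and theoretical stick spectra."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Spectrum", "StickSpectrum"]


@dataclass
class StickSpectrum:
    """A theoretical stick spectrum: m/z positions and relative intensities.

    ``label`` carries provenance (e.g. ``"b5+1"`` for a fragment envelope).
    """

    mz: np.ndarray
    intensity: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have the same shape")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return self.mz.size


@dataclass
class Spectrum:
    """A centroided scan: sorted peak list plus acquisition metadata.

    Retention time is canonically in minutes.  MS2 scans from data-dependent
    acquisition carry ``precursor_mz`` (and optionally charge and isolation
    width).
    """

    mz: np.ndarray
    intensity: np.ndarray
    scan_number: int = 0
    ms_level: int = 2
    retention_time: float = 0.0
    precursor_mz: float | None = None
    precursor_charge: int | None = None
    isolation_width: float | None = None
    peak_charge: np.ndarray | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have the same shape")
        if np.any(self.intensity < 0):
            raise ValueError("negative peak intensity")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        if self.peak_charge is not None:
            self.peak_charge = np.asarray(self.peak_charge)[order]

    def __len__(self) -> int:
        return self.mz.size

    @property
    def tic(self) -> float:
        """Total ion current: summed peak intensity of the scan."""
        return float(self.intensity.sum())
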