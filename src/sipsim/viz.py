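"""Publication-style plots: mirror PSMs, fine structures, and run summaries.

Every plotting function returns the data it drew (a plain dict of arrays)
alongside writing the figure file, so tests assert on the data layer rather
than on pixels.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.figure import Figure

from .fine_structure import FineSpectrum, composition_string, jitter_overlapping_peaks
from .scoring import MatchResult
from .spectra_io import RunSummary
from .spectrum import Spectrum, StickSpectrum

__all__ = ["mirror_plot", "fine_structure_plot", "run_plots"]

MATCHED_COLOR = "#e6b422"  # theoretical envelope (yellow)
OBSERVED_COLOR = "#c0392b"  # observed matched peaks (red)
UNMATCHED_COLOR = "#999999"  # unmatched observed peaks (gray)


def _save(fig: Figure, out_path) -> None:
    Path(out_path).parent.mkdir(parents=True, exist_ok=True)
    FigureCanvasAgg(fig)
    fig.savefig(out_path)


def mirror_plot(
    theoretical: StickSpectrum,
    observed: Spectrum,
    match: MatchResult,
    out_path,
    annotate: bool = True,
    labels: list[str] | None = None,
) -> dict:
    """Theoretical sticks up, observed peaks down; matches highlighted.

    *labels*, if given, annotates each theoretical stick (e.g. ``"b5+1"``);
    with ``annotate=False`` no text labels are drawn.  Returns the plotted
    data layer.
    """
    obs_scale = observed.intensity.max() if len(observed) else 1.0
    obs_norm = observed.intensity / obs_scale * 100.0 if obs_scale > 0 else observed.intensity
    matched_obs = {oi for _, oi in match.pairs}
    data = {
        "theoretical_mz": theoretical.mz,
        "theoretical_intensity": theoretical.intensity,
        "observed_mz": observed.mz,
        "observed_intensity": -obs_norm,
        "matched_theoretical": np.array(sorted(ti for ti, _ in match.pairs), dtype=int),
        "matched_observed": np.array(sorted(matched_obs), dtype=int),
        "labels": [],
    }
    fig = Figure(figsize=(9, 5))
    ax = fig.add_subplot(111)
    ax.vlines(theoretical.mz, 0, theoretical.intensity, color=MATCHED_COLOR, lw=1.2)
    colors = [
        OBSERVED_COLOR if i in matched_obs else UNMATCHED_COLOR for i in range(len(observed))
    ]
    ax.vlines(observed.mz, 0, -obs_norm, color=colors, lw=1.0)
    if annotate and labels is not None:
        for ti, _ in match.pairs:
            if ti < len(labels) and labels[ti]:
                ax.annotate(
                    labels[ti],
                    (theoretical.mz[ti], theoretical.intensity[ti]),
                    fontsize=7,
                    rotation=90,
                    ha="center",
                    va="bottom",
                )
                data["labels"].append(labels[ti])
    ax.axhline(0.0, color="black", lw=0.8)
    ax.set_xlabel("m/z")
    ax.set_ylabel("relative intensity (obs mirrored)")
    _save(fig, out_path)
    return data


def fine_structure_plot(
    fs: FineSpectrum, top_n_labels: int = 5, out_path="fine_structure.png"
) -> dict:
    """Stick plot of isotopologues with the most probable species labeled.

    Near-coincident peaks are displaced for display (gaps >= 0.03 Da by
    default) while the true masses stay in the returned data layer.
    """
    shown = jitter_overlapping_peaks(fs)
    probs = shown.probabilities
    top = np.argsort(-probs)[: min(top_n_labels, len(shown))]
    labels = [composition_string(shown.species[i].composition, fs.table) or "mono" for i in top]
    data = {
        "display_mass": shown.display_mass,
        "true_mass": shown.masses,
        "probability": probs,
        "label_indices": np.sort(top),
        "labels": labels,
    }
    fig = Figure(figsize=(8, 4.5))
    ax = fig.add_subplot(111)
    ax.vlines(shown.display_mass, 0, probs, color="#555555", lw=1.0)
    for i, lab in zip(top, labels):
        ax.annotate(
            lab,
            (shown.display_mass[i], probs[i]),
            color="red",
            fontsize=8,
            ha="center",
            va="bottom",
        )
    ax.set_xlabel("mass (Da)")
    ax.set_ylabel("probability")
    _save(fig, out_path)
    return data


def run_plots(rs: RunSummary, out_dir) -> dict:
    """TIC per level, scan-rate traces, and the precursor map (three files)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data = {"tic": rs.tic, "scan_rate": rs.scan_rate, "precursor_map": rs.precursor_map}

    fig = Figure(figsize=(8, 4))
    ax = fig.add_subplot(111)
    for level, (rt, tic) in rs.tic.items():
        ax.plot(rt, tic, lw=0.9, label=f"MS{level}")
    ax.set_xlabel("retention time (min)")
    ax.set_ylabel("TIC")
    ax.legend()
    _save(fig, out_dir / "tic.png")

    fig = Figure(figsize=(8, 4))
    ax = fig.add_subplot(111)
    for level, (starts, counts) in rs.scan_rate.items():
        color = "red" if level == 1 else "blue"
        ax.step(starts, counts, where="post", color=color, label=f"MS{level}")
    ax.set_xlabel("retention time (min)")
    ax.set_ylabel(f"scans per {rs.time_bin:g} min")
    ax.legend()
    _save(fig, out_dir / "scan_rate.png")

    fig = Figure(figsize=(8, 4))
    ax = fig.add_subplot(111)
    rt, mz = rs.precursor_map
    ax.scatter(rt, mz, s=4, color="#333333")
    ax.set_xlabel("retention time (min)")
    ax.set_ylabel("precursor m/z")
    _save(fig, out_dir / "precursor_map.png")

    data["files"] = [out_dir / "tic.png", out_dir / "scan_rate.png", out_dir / "precursor_map.png"]
    return data
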