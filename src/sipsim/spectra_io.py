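"""Readers and writers for centroided-spectrum and PSM formats.

Supported: FT2 (the plain-text dialect emitted by the Raxport converter —
see ``docs/ft2_format.md`` for the pinned grammar and a worked example),
MGF and mzML (through pyteomics), and tab-separated PSM lists in the style
of the Sipros search engine.  All readers normalize into
:class:`~sipsim.spectrum.Spectrum` with retention times in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .spectrum import Spectrum

__all__ = [
    "FT2ParseError",
    "PSMRow",
    "RunSummary",
    "read_ft2",
    "write_ft2",
    "read_mgf",
    "write_mgf",
    "read_mzml",
    "read_psm_tsv",
    "SIPROS_COLUMNS",
    "summarize_run",
]


class FT2ParseError(ValueError):
    """Malformed FT2 content; the message names the offending line."""


_KNOWN_I = {"RetentionTime", "MSLevel", "IsolationWidth"}


def read_ft2(path) -> list[Spectrum]:
    """Parse an FT2 file into spectra.

    Scan blocks start at an ``S`` line (scan number, scan number, optional
    precursor m/z); ``I`` lines carry metadata (RetentionTime in minutes,
    MSLevel, IsolationWidth are interpreted; unknown keys are preserved
    verbatim in ``Spectrum.extra``); ``Z`` lines carry precursor charge and
    neutral mass; remaining lines are m/z–intensity pairs with optional
    resolution/baseline/noise/charge columns.
    """
    spectra: list[Spectrum] = []
    current: dict | None = None

    def flush():
        nonlocal current
        if current is None:
            return
        peaks = current.pop("peaks")
        charges = current.pop("peak_charges")
        mz = np.array([p[0] for p in peaks])
        inten = np.array([p[1] for p in peaks])
        peak_charge = np.array(charges) if any(c is not None for c in charges) else None
        if peak_charge is not None:
            peak_charge = np.array([c if c is not None else 0 for c in charges])
        spectra.append(Spectrum(mz=mz, intensity=inten, peak_charge=peak_charge, **current))
        current = None

    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("H"):
            continue
        fields = line.split("\t")
        tag = fields[0]
        if tag == "S":
            flush()
            try:
                scan = int(fields[1])
                precursor = float(fields[3]) if len(fields) > 3 and fields[3] else None
            except (IndexError, ValueError):
                raise FT2ParseError(f"line {lineno}: malformed S line {line!r}") from None
            current = {
                "scan_number": scan,
                "ms_level": 2 if precursor is not None else 1,
                "precursor_mz": precursor,
                "retention_time": 0.0,
                "precursor_charge": None,
                "isolation_width": None,
                "extra": {},
                "peaks": [],
                "peak_charges": [],
            }
        elif tag == "I":
            if current is None:
                raise FT2ParseError(f"line {lineno}: I line outside a scan block")
            key = fields[1] if len(fields) > 1 else ""
            value = fields[2] if len(fields) > 2 else ""
            if key == "RetentionTime":
                current["retention_time"] = float(value)
            elif key == "MSLevel":
                current["ms_level"] = int(value)
            elif key == "IsolationWidth":
                current["isolation_width"] = float(value)
            else:
                current["extra"][key] = value
        elif tag == "Z":
            if current is None:
                raise FT2ParseError(f"line {lineno}: Z line outside a scan block")
            try:
                current["precursor_charge"] = int(fields[1])
                current["extra"]["neutral_mass"] = float(fields[2])
            except (IndexError, ValueError):
                raise FT2ParseError(f"line {lineno}: malformed Z line {line!r}") from None
        else:
            if current is None:
                raise FT2ParseError(f"line {lineno}: peak line outside a scan block")
            try:
                mz = float(fields[0])
                inten = float(fields[1])
            except (IndexError, ValueError):
                raise FT2ParseError(f"line {lineno}: malformed peak line {line!r}") from None
            charge = None
            if len(fields) >= 6 and fields[5]:
                try:
                    charge = int(float(fields[5]))
                except ValueError:
                    charge = None
            current["peaks"].append((mz, inten))
            current["peak_charges"].append(charge)
    flush()
    return spectra


def write_ft2(spectra: list[Spectrum], path) -> None:
    """Write spectra in the FT2 dialect read by :func:`read_ft2`."""
    lines = ["H\tExtractor\tsipsim"]
    for s in spectra:
        if s.precursor_mz is not None:
            lines.append(f"S\t{s.scan_number}\t{s.scan_number}\t{s.precursor_mz:.10g}")
        else:
            lines.append(f"S\t{s.scan_number}\t{s.scan_number}")
        lines.append(f"I\tRetentionTime\t{s.retention_time:.10g}")
        lines.append(f"I\tMSLevel\t{s.ms_level}")
        if s.isolation_width is not None:
            lines.append(f"I\tIsolationWidth\t{s.isolation_width:.10g}")
        for key, value in s.extra.items():
            if key not in _KNOWN_I and key != "neutral_mass":
                lines.append(f"I\t{key}\t{value}")
        if s.precursor_charge is not None:
            neutral = s.extra.get("neutral_mass", 0.0)
            lines.append(f"Z\t{s.precursor_charge}\t{float(neutral):.10g}")
        for i in range(len(s)):
            lines.append(f"{s.mz[i]:.10g}\t{s.intensity[i]:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")


def _charge_from_mgf(params) -> int | None:
    charge = params.get("charge")
    if charge is None:
        return None
    try:
        return int(charge[0])
    except (TypeError, IndexError):
        return int(charge)


def read_mgf(path) -> list[Spectrum]:
    """Read MGF BEGIN/END IONS blocks (PEPMASS, CHARGE, RTINSECONDS honored)."""
    from pyteomics import mgf

    spectra = []
    with mgf.MGF(str(path)) as reader:
        for i, entry in enumerate(reader, start=1):
            params = entry["params"]
            pepmass = params.get("pepmass")
            precursor = float(pepmass[0]) if pepmass else None
            rt = params.get("rtinseconds")
            scan = params.get("scans")
            spectra.append(
                Spectrum(
                    mz=np.asarray(entry["m/z array"], float),
                    intensity=np.asarray(entry["intensity array"], float),
                    scan_number=int(scan) if scan is not None else i,
                    ms_level=2 if precursor is not None else 1,
                    retention_time=float(rt) / 60.0 if rt is not None else 0.0,
                    precursor_mz=precursor,
                    precursor_charge=_charge_from_mgf(params),
                    extra={"title": params.get("title", "")},
                )
            )
    return spectra


def write_mgf(spectra: list[Spectrum], path) -> None:
    from pyteomics import mgf

    entries = []
    for s in spectra:
        params = {
            "title": s.extra.get("title", f"scan={s.scan_number}"),
            "scans": str(s.scan_number),
            "rtinseconds": s.retention_time * 60.0,
        }
        if s.precursor_mz is not None:
            params["pepmass"] = s.precursor_mz
        if s.precursor_charge is not None:
            params["charge"] = s.precursor_charge
        entries.append(
            {"m/z array": s.mz, "intensity array": s.intensity, "params": params}
        )
    mgf.write(entries, output=str(path), file_mode="w")


def _decode_binary_array(elem, ns: str) -> np.ndarray:
    import base64
    import zlib

    accessions = {
        cv.get("accession") for cv in elem.findall(f"{ns}cvParam")
    }
    binary = elem.find(f"{ns}binary")
    raw = base64.b64decode(binary.text or "")
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"  # 32- vs 64-bit float
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path) -> list[Spectrum]:
    """Read centroided spectra from an mzML document (lxml-based).

    Handles the controlled-vocabulary terms that matter here: ms level, scan
    start time (minute/second units), selected-ion m/z and charge, and
    base64 binary arrays (64- or 32-bit float, optionally zlib-compressed).
    """
    from lxml import etree

    tree = etree.parse(str(path))
    root = tree.getroot()
    ns = ""
    if root.tag.startswith("{"):
        ns = root.tag[: root.tag.index("}") + 1]

    def cv_map(elem):
        return {
            cv.get("accession"): cv
            for cv in elem.findall(f"{ns}cvParam")
        }

    spectra = []
    for i, spec in enumerate(root.iter(f"{ns}spectrum"), start=1):
        cvs = cv_map(spec)
        ms_level = int(cvs["MS:1000511"].get("value")) if "MS:1000511" in cvs else 1
        rt = 0.0
        scan = spec.find(f"{ns}scanList/{ns}scan")
        if scan is not None:
            scan_cvs = cv_map(scan)
            if "MS:1000016" in scan_cvs:
                cv = scan_cvs["MS:1000016"]
                rt = float(cv.get("value"))
                if cv.get("unitName", "minute").startswith("second"):
                    rt /= 60.0
        precursor = None
        precursor_charge = None
        ion = spec.find(
            f"{ns}precursorList/{ns}precursor/{ns}selectedIonList/{ns}selectedIon"
        )
        if ion is not None:
            ion_cvs = cv_map(ion)
            if "MS:1000744" in ion_cvs:
                precursor = float(ion_cvs["MS:1000744"].get("value"))
            if "MS:1000041" in ion_cvs:
                precursor_charge = int(ion_cvs["MS:1000041"].get("value"))
        mz = np.array([])
        inten = np.array([])
        for arr in spec.findall(f"{ns}binaryDataArrayList/{ns}binaryDataArray"):
            arr_cvs = cv_map(arr)
            if "MS:1000514" in arr_cvs:  # m/z array
                mz = _decode_binary_array(arr, ns)
            elif "MS:1000515" in arr_cvs:  # intensity array
                inten = _decode_binary_array(arr, ns)
        scan_number = i
        for token in (spec.get("id") or "").split():
            if token.startswith("scan="):
                scan_number = int(token[5:])
        spectra.append(
            Spectrum(
                mz=mz,
                intensity=inten,
                scan_number=scan_number,
                ms_level=ms_level,
                retention_time=rt,
                precursor_mz=precursor,
                precursor_charge=precursor_charge,
            )
        )
    return spectra


@dataclass
class PSMRow:
    """A PSM-list row: the skeleton needed to rescore or visualize a match."""

    scan: int
    sequence: str
    charge: int
    score: float | None = None
    enrichment: float | None = None
    raw: dict = field(default_factory=dict)


#: Default column mapping for Sipros-style PSM TSV files.
SIPROS_COLUMNS = {
    "scan": "ScanNumber",
    "peptide": "IdentifiedPeptide",
    "charge": "ParentCharge",
    "score": "Score",
    "enrichment": "Enrichment",  # optional; percent if > 1 else fraction
}


def _strip_peptide(text: str) -> str:
    """Strip flanking residues (``K.PEPTIDE.R``) and modification symbols."""
    parts = text.split(".")
    if len(parts) == 3 and len(parts[0]) <= 2 and len(parts[2]) <= 2:
        text = parts[1]
    return "".join(ch for ch in text if ch.isalpha() and ch.isupper())


def read_psm_tsv(path, column_map: dict | None = None) -> list[PSMRow]:
    """Read a tab-separated PSM list with a configurable column mapping."""
    import pandas as pd

    cols = dict(SIPROS_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep="\t", comment="#")
    for key in ("scan", "peptide", "charge"):
        if cols[key] not in df.columns:
            raise KeyError(
                f"required column {cols[key]!r} missing; available: {list(df.columns)}"
            )
    rows = []
    for _, rec in df.iterrows():
        score = rec.get(cols["score"])
        enrichment = rec.get(cols["enrichment"])
        if enrichment is not None and not pd.isna(enrichment):
            enrichment = float(enrichment)
            if enrichment > 1.0:
                enrichment /= 100.0
        else:
            enrichment = None
        rows.append(
            PSMRow(
                scan=int(rec[cols["scan"]]),
                sequence=_strip_peptide(str(rec[cols["peptide"]])),
                charge=int(rec[cols["charge"]]),
                score=float(score) if score is not None and not pd.isna(score) else None,
                enrichment=enrichment,
                raw=rec.to_dict(),
            )
        )
    return rows


@dataclass
class RunSummary:
    """Per-MS-level TIC and scan-rate traces plus the MS2 precursor map."""

    tic: dict[int, tuple[np.ndarray, np.ndarray]]  # level -> (rt, summed intensity)
    scan_rate: dict[int, tuple[np.ndarray, np.ndarray]]  # level -> (bin starts, counts)
    precursor_map: tuple[np.ndarray, np.ndarray]  # (rt, precursor m/z) of MS2 scans
    time_bin: float = 1.0


def summarize_run(scans: list[Spectrum], time_bin: float = 1.0) -> RunSummary:
    """Summarize an LC–MS/MS run: TIC, scan acquisition rate, precursor map."""
    levels = sorted({s.ms_level for s in scans})
    tic = {}
    rate = {}
    all_rt = [s.retention_time for s in scans]
    t_max = max(all_rt) if all_rt else 0.0
    edges = np.arange(0.0, t_max + time_bin, time_bin)
    if edges.size < 2:
        edges = np.array([0.0, time_bin])
    for level in levels:
        sel = [s for s in scans if s.ms_level == level]
        rts = np.array([s.retention_time for s in sel])
        tics = np.array([s.tic for s in sel])
        order = np.argsort(rts, kind="stable")
        tic[level] = (rts[order], tics[order])
        counts, _ = np.histogram(rts, bins=edges)
        rate[level] = (edges[:-1], counts)
    ms2 = [s for s in scans if s.ms_level == 2 and s.precursor_mz is not None]
    precursor_map = (
        np.array([s.retention_time for s in ms2]),
        np.array([s.precursor_mz for s in ms2]),
    )
    return RunSummary(tic=tic, scan_rate=rate, precursor_map=precursor_map, time_bin=time_bin)
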