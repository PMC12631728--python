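import base64
import struct
import zlib

import numpy as np
import pytest

from sipsim.spectra_io import (
    FT2ParseError,
    read_ft2,
    read_mgf,
    read_mzml,
    read_psm_tsv,
    summarize_run,
    write_ft2,
    write_mgf,
)
from sipsim.spectrum import Spectrum
from sipsim.synthetic import make_run


@pytest.fixture(scope="module")
def run():
    return make_run(n_ms1=5, n_ms2_per_ms1=4, gradient_minutes=2.0, seed=9)


class TestFT2:
    def test_round_trip(self, run, tmp_path):
        path = tmp_path / "run.ft2"
        write_ft2(run, path)
        back = read_ft2(path)
        assert len(back) == len(run)
        for a, b in zip(run, back):
            assert b.scan_number == a.scan_number
            assert b.ms_level == a.ms_level
            assert len(b) == len(a)
            assert b.mz == pytest.approx(a.mz, rel=1e-6)
            assert b.intensity == pytest.approx(a.intensity, rel=1e-6)
            assert b.retention_time == pytest.approx(a.retention_time, rel=1e-6)
            if a.precursor_mz is not None:
                assert b.precursor_mz == pytest.approx(a.precursor_mz, rel=1e-6)
                assert b.precursor_charge == a.precursor_charge

    def test_unknown_metadata_preserved(self, tmp_path):
        s = Spectrum(mz=[100.0], intensity=[1.0], scan_number=3, ms_level=1,
                     extra={"Instrument": "Orbitrap Fusion"})
        path = tmp_path / "meta.ft2"
        write_ft2([s], path)
        assert read_ft2(path)[0].extra["Instrument"] == "Orbitrap Fusion"

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.ft2"
        path.write_text("")
        assert read_ft2(path) == []

    def test_malformed_s_line_names_line(self, tmp_path):
        path = tmp_path / "bad.ft2"
        path.write_text("S\tnotanumber\t2\n")
        with pytest.raises(FT2ParseError, match="line 1"):
            read_ft2(path)

    def test_truncated_peak_line_names_line(self, tmp_path):
        path = tmp_path / "trunc.ft2"
        path.write_text("S\t1\t1\n100.5\n")
        with pytest.raises(FT2ParseError, match="line 2"):
            read_ft2(path)

    def test_peak_outside_block(self, tmp_path):
        path = tmp_path / "orphan.ft2"
        path.write_text("100.5\t20\n")
        with pytest.raises(FT2ParseError):
            read_ft2(path)


class TestMGF:
    def test_round_trip(self, run, tmp_path):
        ms2 = [s for s in run if s.ms_level == 2]
        path = tmp_path / "run.mgf"
        write_mgf(ms2, path)
        back = read_mgf(path)
        assert len(back) == len(ms2)
        for a, b in zip(ms2, back):
            assert b.precursor_mz == pytest.approx(a.precursor_mz, rel=1e-6)
            assert b.precursor_charge == a.precursor_charge
            assert b.mz == pytest.approx(a.mz, rel=1e-6)
            assert b.intensity == pytest.approx(a.intensity, rel=1e-6)
            assert b.retention_time == pytest.approx(a.retention_time, rel=1e-6)

    def test_pepmass_honored(self, tmp_path):
        path = tmp_path / "one.mgf"
        path.write_text(
            "BEGIN IONS\nTITLE=t\nPEPMASS=950.9609\nCHARGE=2+\nRTINSECONDS=60\n"
            "100.0 10.0\n200.0 20.0\nEND IONS\n"
        )
        s = read_mgf(path)[0]
        assert s.precursor_mz == pytest.approx(950.9609)
        assert s.precursor_charge == 2
        assert s.retention_time == pytest.approx(1.0)

    def test_empty_mgf(self, tmp_path):
        path = tmp_path / "none.mgf"
        path.write_text("")
        assert read_mgf(path) == []


def minimal_mzml(spectra) -> str:
    """Build a small conformant mzML document (synthetic, for reader tests)."""

    def encode(arr):
        return base64.b64encode(
            zlib.compress(struct.pack(f"<{len(arr)}d", *arr))
        ).decode()

    blocks = []
    for i, (mz, inten, precursor) in enumerate(spectra, start=1):
        prec = ""
        if precursor is not None:
            prec = f"""
        <precursorList count="1"><precursor><selectedIonList count="1"><selectedIon>
          <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{precursor}"/>
          <cvParam cvRef="MS" accession="MS:1000041" name="charge state" value="2"/>
        </selectedIon></selectedIonList></precursor></precursorList>"""
        level = 1 if precursor is None else 2
        blocks.append(f"""
      <spectrum index="{i - 1}" id="scan={i}" defaultArrayLength="{len(mz)}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{level}"/>
        <scanList count="1"><scan>
          <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{i * 0.5}" unitName="minute"/>
        </scan></scanList>{prec}
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="0">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>
            <cvParam cvRef="MS" accession="MS:1000574" name="zlib compression"/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array"/>
            <binary>{encode(mz)}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="0">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>
            <cvParam cvRef="MS" accession="MS:1000574" name="zlib compression"/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array"/>
            <binary>{encode(inten)}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>""")
    inner = "".join(blocks)
    return f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <run id="synthetic">
    <spectrumList count="{len(spectra)}" defaultDataProcessingRef="dp">{inner}
    </spectrumList>
  </run>
</mzML>"""


class TestMzML:
    def test_reads_synthetic_document(self, tmp_path):
        doc = minimal_mzml(
            [
                ([100.0, 200.0, 300.0], [10.0, 20.0, 30.0], None),
                ([150.5, 250.5], [5.0, 15.0], 950.9609),
            ]
        )
        path = tmp_path / "tiny.mzml"
        path.write_text(doc)
        spectra = read_mzml(path)
        assert len(spectra) == 2
        assert spectra[0].ms_level == 1
        assert spectra[0].mz == pytest.approx([100.0, 200.0, 300.0])
        assert spectra[1].ms_level == 2
        assert spectra[1].precursor_mz == pytest.approx(950.9609)
        assert spectra[1].precursor_charge == 2
        assert spectra[1].retention_time == pytest.approx(1.0)
        assert spectra[1].scan_number == 2


class TestPSMTable:
    def write_fixture(self, tmp_path):
        path = tmp_path / "psm.tsv"
        path.write_text(
            "ScanNumber\tIdentifiedPeptide\tParentCharge\tScore\tEnrichment\n"
            "101\tK.PEPTIDE.R\t2\t42.5\t50\n"
            "102\t[HYAHVDCPGHADYVK]\t3\t17.0\t1.07\n"
            "103\tAG{15.99}K\t2\t\t\n"
        )
        return path

    def test_three_rows_parsed(self, tmp_path):
        rows = read_psm_tsv(self.write_fixture(tmp_path))
        assert len(rows) == 3
        assert [r.scan for r in rows] == [101, 102, 103]

    def test_flanks_and_mods_stripped(self, tmp_path):
        rows = read_psm_tsv(self.write_fixture(tmp_path))
        assert rows[0].sequence == "PEPTIDE"
        assert rows[1].sequence == "HYAHVDCPGHADYVK"
        assert rows[2].sequence == "AGK"

    def test_percent_enrichment_normalized(self, tmp_path):
        rows = read_psm_tsv(self.write_fixture(tmp_path))
        assert rows[0].enrichment == pytest.approx(0.5)
        assert rows[1].enrichment == pytest.approx(0.0107)
        assert rows[2].enrichment is None

    def test_missing_column_lists_available(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("Scan\tPeptide\n1\tAAA\n")
        with pytest.raises(KeyError, match="available"):
            read_psm_tsv(path)

    def test_custom_column_map(self, tmp_path):
        path = tmp_path / "custom.tsv"
        path.write_text("scan_id\tseq\tz\n7\tAGK\t2\n")
        rows = read_psm_tsv(
            path, column_map={"scan": "scan_id", "peptide": "seq", "charge": "z"}
        )
        assert rows[0].sequence == "AGK" and rows[0].charge == 2


class TestRunSummary:
    def test_scan_rates(self):
        scans = make_run(n_ms1=10, n_ms2_per_ms1=4, gradient_minutes=1.0, seed=1)
        rs = summarize_run(scans, time_bin=1.0)
        assert rs.scan_rate[1][1].sum() == 10
        assert rs.scan_rate[2][1].sum() == 40

    def test_tic_conserves_intensity(self, run):
        rs = summarize_run(run)
        for level in (1, 2):
            total = sum(s.tic for s in run if s.ms_level == level)
            assert rs.tic[level][1].sum() == pytest.approx(total, rel=1e-12)

    def test_empty_scan_contributes_zero(self):
        scans = [
            Spectrum(mz=[], intensity=[], ms_level=1, retention_time=0.1),
            Spectrum(mz=[100.0], intensity=[5.0], ms_level=1, retention_time=0.2),
        ]
        rs = summarize_run(scans)
        assert rs.tic[1][1].tolist() == [0.0, 5.0]

    def test_precursor_map_counts_ms2(self, run):
        rs = summarize_run(run)
        n_ms2 = sum(1 for s in run if s.ms_level == 2 and s.precursor_mz is not None)
        assert rs.precursor_map[0].size == n_ms2
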