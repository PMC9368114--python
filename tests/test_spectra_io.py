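"""Peak CSV / mzML ingestion and feature-matrix TSV round-trips."""

import base64
import zlib

import numpy as np
import pandas as pd
import pytest

from insectprint.preprocessing import preprocess_block
from insectprint.spectra_io import (
    SampleRecord,
    Spectrum,
    file_checksum,
    range_check,
    read_feature_matrix,
    read_mzml,
    read_peak_csv,
    write_feature_matrix,
    write_peak_csv,
)


def test_minimal_csv(tmp_path):
    path = tmp_path / "two_rows.csv"
    path.write_text(
        "sample_id,species,extraction,polarity,replicate,mz,intensity\n"
        "S1,Bombyx mori,A,neg,1,100.0,10\n"
        "S1,Bombyx mori,A,neg,1,200.0,20\n"
    )
    samples, spectra = read_peak_csv(path)
    assert [s.species for s in samples] == ["Bombyx mori"]
    assert len(spectra) == 1 and spectra[0].mz.tolist() == [100.0, 200.0]


def test_unknown_species_names_closed_set(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text(
        "sample_id,species,extraction,polarity,replicate,mz,intensity\n"
        "S1,Gryllus,A,neg,1,100.0,10\n"
    )
    with pytest.raises(ValueError, match="Acheta domesticus"):
        read_peak_csv(path)


@pytest.mark.parametrize(
    "row, match",
    [
        ("S1,Bombyx mori,A,neg,5,100.0,10", "replicate"),
        ("S1,Bombyx mori,A,neg,1,xx,10", "non-numeric mz"),
    ],
)
def test_malformed_rows_report_row_number(tmp_path, row, match):
    path = tmp_path / "bad.csv"
    path.write_text(
        "sample_id,species,extraction,polarity,replicate,mz,intensity\n" + row + "\n"
    )
    with pytest.raises(ValueError, match=match):
        read_peak_csv(path)


def test_missing_column(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("sample_id,species,mz\nS1,Bombyx mori,100\n")
    with pytest.raises(ValueError, match="missing columns"):
        read_peak_csv(path)


def test_cohort_round_trip(tmp_path, small_cohort):
    """Write -> read preserves ordering, peak counts and total intensity."""
    samples, spectra = small_cohort
    path = tmp_path / "cohort.csv"
    write_peak_csv(path, samples, spectra)
    samples2, spectra2 = read_peak_csv(path)
    assert [s.sample_id for s in samples2] == [s.sample_id for s in samples]
    assert [s.key for s in spectra2] == [s.key for s in spectra]
    for a, b in zip(spectra, spectra2):
        assert a.mz.size == b.mz.size
        # totals conserved at the written precision
        assert b.total_intensity() == pytest.approx(a.total_intensity(), rel=1e-5)
        assert np.allclose(a.mz, b.mz, atol=1e-6)


def test_write_is_bit_stable(tmp_path, small_cohort):
    samples, spectra = small_cohort
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    write_peak_csv(p1, samples, spectra)
    write_peak_csv(p2, samples, spectra)
    assert file_checksum(p1) == file_checksum(p2)


def test_range_check_flags_but_keeps():
    spec = Spectrum("S1", "A", "neg", 1, mz=[50.0, 100.0, 1200.0], intensity=[1, 2, 3])
    report = range_check([spec])
    assert report == {("S1", "meohneg", 1): 2}
    assert spec.mz.size == 3


def _mzml_bytes(mz, intensity, polarity_accession="MS:1000130", mode="centroid spectrum"):
    def encode(arr):
        raw = np.asarray(arr, dtype="<f8").tobytes()
        return base64.b64encode(zlib.compress(raw)).decode()

    return f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <run id="r1">
    <spectrumList count="1">
      <spectrum index="0" id="scan=1" defaultArrayLength="{len(mz)}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <cvParam cvRef="MS" accession="{'MS:1000127' if mode == 'centroid spectrum' else 'MS:1000128'}" name="{mode}" value=""/>
        <cvParam cvRef="MS" accession="{polarity_accession}" name="{'positive scan' if polarity_accession == 'MS:1000130' else 'negative scan'}" value=""/>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="0">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
            <binary>{encode(mz)}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="0">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
            <binary>{encode(intensity)}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
    </spectrumList>
  </run>
</mzML>
"""


def test_read_mzml_minimal(tmp_path):
    path = tmp_path / "one.mzML"
    path.write_text(_mzml_bytes([100.0, 200.0, 300.0], [1.0, 2.0, 3.0]))
    spectra = read_mzml(path, sample_id="S1", extraction="A", replicate=1)
    assert len(spectra) == 1
    s = spectra[0]
    assert s.polarity == "pos" and s.mz.tolist() == [100.0, 200.0, 300.0]


def test_read_mzml_rejects_profile(tmp_path):
    path = tmp_path / "profile.mzML"
    path.write_text(_mzml_bytes([100.0], [1.0], mode="profile spectrum"))
    with pytest.raises(ValueError, match="centroid"):
        read_mzml(path, "S1", "A", 1)


def test_read_mzml_negative_polarity(tmp_path):
    path = tmp_path / "neg.mzML"
    path.write_text(_mzml_bytes([100.0], [1.0], polarity_accession="MS:1000129"))
    (s,) = read_mzml(path, "S1", "B", 2)
    assert s.polarity == "neg" and s.block == "etacneg"


def test_feature_matrix_round_trip(tmp_path, small_cohort):
    _, spectra = small_cohort
    block = [s for s in spectra if s.block == "meohneg"]
    matrix = preprocess_block(block)
    path = tmp_path / "m.tsv"
    write_feature_matrix(matrix, path)
    back = read_feature_matrix(path)
    assert back.block == matrix.block
    assert back.scaling_state == matrix.scaling_state
    assert np.allclose(back.bin_mz, np.round(matrix.bin_mz, 4))
    assert np.allclose(
        back.values.to_numpy(float), matrix.values.to_numpy(float), rtol=1e-9
    )
    # bit-stable re-write
    path2 = tmp_path / "m2.tsv"
    write_feature_matrix(back, path2)
    path3 = tmp_path / "m3.tsv"
    write_feature_matrix(back, path3)
    assert file_checksum(path2) == file_checksum(path3)


def test_feature_matrix_duplicate_headers(tmp_path):
    path = tmp_path / "dup.tsv"
    path.write_text(
        "sample_id\treplicate\tblock\t100.0000\t100.0000\n"
        "s0\t1\tmeohneg\t1.0\t2.0\n"
    )
    with pytest.raises(ValueError, match="duplicate bin headers"):
        read_feature_matrix(path)


def test_empty_matrix_rejected(tmp_path):
    path = tmp_path / "empty.tsv"
    path.write_text("sample_id\treplicate\tblock\t100.0000\n")
    with pytest.raises(ValueError, match="empty"):
        read_feature_matrix(path)


def test_sample_record_validation():
    with pytest.raises(ValueError, match="unknown species"):
        SampleRecord("S1", "Gryllus assimilis")
    with pytest.raises(ValueError, match="role"):
        SampleRecord("S1", "Bombyx mori", "validation")
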