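import base64
import struct
import zlib

import numpy as np
import pytest

from myfrquant import msio
from myfrquant.features import Feature
from myfrquant.msio import Run, Spectrum, SchemaError, UnsupportedDataError


def _spec(rt, mz, inten, ms_level=1, polarity="negative", precursor=None):
    return Spectrum(
        rt=rt,
        ms_level=ms_level,
        polarity=polarity,
        mz=np.array(mz, dtype=float),
        intensity=np.array(inten, dtype=float),
        precursor_mz=precursor,
    )


@pytest.fixture
def small_run():
    return Run(
        spectra=[
            _spec(10.0, [128.0353, 500.123456789, 999.9], [100.0, 2500.5, 3.0]),
            _spec(11.0, [], []),
            _spec(
                11.5,
                [213.0910, 230.1176],
                [800.0, 1000.0],
                ms_level=2,
                polarity="positive",
                precursor=247.1441,
            ),
            _spec(12.0, [128.0353], [90.0]),
        ],
        metadata={"polarity": "negative"},
    )


def test_mzml_round_trip(tmp_path, small_run):
    path = tmp_path / "run.mzml"
    msio.write_mzml(small_run, path)
    back = msio.read_mzml(path)
    assert len(back.spectra) == len(small_run.spectra)
    for a, b in zip(small_run.spectra, back.spectra):
        assert np.array_equal(a.mz, b.mz)  # 64-bit: bit-exact
        assert b.intensity == pytest.approx(a.intensity, rel=1e-6)  # 32-bit
        assert b.rt == pytest.approx(a.rt, abs=1e-9)
        assert b.ms_level == a.ms_level
        assert b.polarity == a.polarity
        if a.ms_level == 2:
            assert b.precursor_mz == pytest.approx(a.precursor_mz, abs=1e-9)


def test_mzml_empty_run_round_trip(tmp_path):
    path = tmp_path / "empty.mzml"
    msio.write_mzml(Run(), path)
    back = msio.read_mzml(path)
    assert back.spectra == []


def test_write_rejects_unsorted_peaks(tmp_path):
    bad = Run(spectra=[_spec(1.0, [500.0, 400.0], [1.0, 2.0])])
    with pytest.raises(ValueError, match="sorted"):
        msio.write_mzml(bad, tmp_path / "bad.mzml")


def _handcrafted_mzml(spectrum_blocks):
    return (
        '<?xml version="1.0" encoding="utf-8"?>\n'
        '<indexedmzML xmlns="http://psi.hupo.org/ms/mzml">\n'
        '<mzML id="x" version="1.1.0">\n<run id="r">\n'
        f'<spectrumList count="{len(spectrum_blocks)}">\n'
        + "\n".join(spectrum_blocks)
        + "\n</spectrumList>\n</run>\n</mzML>\n</indexedmzML>\n"
    )


def test_reader_on_handcrafted_file(tmp_path):
    """Reader correctness against a file written by hand, not by our writer:
    zlib-compressed 64-bit m/z, 32-bit intensities, RT in minutes."""
    mz = [400.25, 612.125]
    inten = [1500.0, 80.0]
    mz_b64 = base64.b64encode(zlib.compress(struct.pack("<2d", *mz))).decode()
    int_b64 = base64.b64encode(struct.pack("<2f", *inten)).decode()
    block = f"""<spectrum index="0" id="scan=1" defaultArrayLength="2">
<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
<cvParam cvRef="MS" accession="MS:1000129" name="negative scan" value=""/>
<scanList count="1"><scan>
<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="0.5" unitName="minute"/>
</scan></scanList>
<binaryDataArrayList count="2">
<binaryDataArray encodedLength="{len(mz_b64)}">
<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
<cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>
<cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
<binary>{mz_b64}</binary></binaryDataArray>
<binaryDataArray encodedLength="{len(int_b64)}">
<cvParam cvRef="MS" accession="MS:1000521" name="32-bit float" value=""/>
<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
<cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
<binary>{int_b64}</binary></binaryDataArray>
</binaryDataArrayList></spectrum>"""
    path = tmp_path / "hand.mzml"
    path.write_text(_handcrafted_mzml([block]))
    run = msio.read_mzml(path)
    assert len(run.spectra) == 1
    s = run.spectra[0]
    assert s.rt == pytest.approx(30.0)  # minutes converted to seconds
    assert s.polarity == "negative"
    assert np.allclose(s.mz, mz)
    assert np.allclose(s.intensity, inten)


def test_reader_rejects_profile_spectra(tmp_path):
    block = """<spectrum index="0" id="scan=1" defaultArrayLength="0">
<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
<cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum" value=""/>
<scanList count="1"><scan>
<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="1.0" unitName="second"/>
</scan></scanList>
</spectrum>"""
    path = tmp_path / "profile.mzml"
    path.write_text(_handcrafted_mzml([block]))
    with pytest.raises(UnsupportedDataError):
        msio.read_mzml(path)


def _random_features(n, rng):
    out = []
    for i in range(n):
        rt = float(rng.uniform(10, 100))
        out.append(
            Feature(
                feature_id=i,
                mz=float(rng.uniform(120, 1200)),
                rt_start=rt - 5,
                rt_apex=rt,
                rt_end=rt + 5,
                area=float(rng.uniform(1e3, 1e6)),
                apex_intensity=float(rng.uniform(10, 1e5)),
                charge=int(rng.integers(1, 9)) if rng.random() < 0.7 else None,
                monoisotopic=bool(rng.random() < 0.8),
            )
        )
    return out


def test_feature_table_round_trip(tmp_path):
    rng = np.random.default_rng(3)
    feats = _random_features(100, rng)
    path = tmp_path / "features.tsv"
    msio.write_feature_table(feats, path)
    back = msio.read_feature_table(path)
    assert len(back) == 100
    for a, b in zip(feats, back):
        assert b.feature_id == a.feature_id
        assert b.mz == pytest.approx(a.mz, rel=1e-6)
        assert b.charge == a.charge
        assert b.monoisotopic == a.monoisotopic
        assert b.area == pytest.approx(a.area, rel=1e-6)
        assert b.rt_start <= b.rt_apex <= b.rt_end


def test_feature_table_blank_charge_means_unannotated(tmp_path):
    f = Feature(0, 500.0, 10.0, 12.0, 14.0, 1e4, 500.0, charge=None)
    path = tmp_path / "one.tsv"
    msio.write_feature_table([f], path)
    text = path.read_text()
    assert "\t\t" in text or "\t\n" in text  # blank charge cell
    back = msio.read_feature_table(path)
    assert back[0].charge is None


def test_feature_table_empty(tmp_path):
    path = tmp_path / "empty.tsv"
    msio.write_feature_table([], path)
    assert msio.read_feature_table(path) == []


def test_feature_table_missing_column_raises(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("feature_id\tmz\tcharge\n0\t500.0\t1\n")
    with pytest.raises(SchemaError, match="rt_start"):
        msio.read_feature_table(path)
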