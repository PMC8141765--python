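"""Read/write centroided LC-MS runs (mzML) and feature tables (TSV).

Both directions are implemented here on top of :mod:`lxml`: a streaming
reader that resolves the PSI-MS controlled-vocabulary terms it needs by
accession, and an indexed-mzML emitter (64-bit m/z arrays, 32-bit intensity
arrays, centroid-spectrum annotation).  m/z arrays round-trip bit-exactly;
zlib-compressed input is supported, output is uncompressed.

Retention times are seconds everywhere in memory; files using minutes are
converted on read.  Only centroid data are supported — profile spectra
raise :class:`UnsupportedDataError` instead of being silently mis-processed.
"""

from __future__ import annotations

import base64
import hashlib
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from lxml import etree

__all__ = [
    "Spectrum",
    "Run",
    "UnsupportedDataError",
    "SchemaError",
    "read_mzml",
    "write_mzml",
    "FEATURE_COLUMNS",
    "read_feature_table",
    "write_feature_table",
]


class UnsupportedDataError(ValueError):
    """Input data the pipeline must not silently process (e.g. profile mode)."""


class SchemaError(ValueError):
    """A table is missing required columns."""


@dataclass
class Spectrum:
    """One centroided scan.

    ``mz`` is float64 and strictly increasing; ``intensity`` is non-negative
    and the same length.  ``precursor_mz`` is present iff ``ms_level == 2``.
    """

    rt: float
    ms_level: int
    polarity: str
    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: Optional[float] = None

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays must have equal length")
        if (self.ms_level == 2) != (self.precursor_mz is not None):
            raise ValueError("precursor_mz must be present iff ms_level == 2")

    def validate(self) -> None:
        if len(self.mz) > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("peaks must be sorted strictly increasing in m/z")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be >= 0")


@dataclass
class Run:
    """An ordered collection of spectra with non-decreasing RT."""

    spectra: List[Spectrum] = field(default_factory=list)
    metadata: Dict = field(default_factory=dict)

    def validate(self) -> None:
        rts = [s.rt for s in self.spectra]
        if any(b < a for a, b in zip(rts, rts[1:])):
            raise ValueError("spectrum RTs must be non-decreasing")
        for s in self.spectra:
            s.validate()

    def ms1(self) -> List[Spectrum]:
        return [s for s in self.spectra if s.ms_level == 1]

    def ms2(self) -> List[Spectrum]:
        return [s for s in self.spectra if s.ms_level == 2]


# PSI-MS accessions resolved by the reader (no full CV needed)
_ACC_MS_LEVEL = "MS:1000511"
_ACC_CENTROID = "MS:1000127"
_ACC_PROFILE = "MS:1000128"
_ACC_NEGATIVE = "MS:1000129"
_ACC_POSITIVE = "MS:1000130"
_ACC_SCAN_START = "MS:1000016"
_ACC_SELECTED_MZ = "MS:1000744"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"


def _localname(el) -> str:
    tag = el.tag
    return tag.rsplit("}", 1)[-1] if "}" in tag else tag


def _iter_cvparams(el):
    for sub in el.iter():
        if _localname(sub) == "cvParam":
            yield sub


def _decode_binary_array(bda) -> np.ndarray:
    dtype = "<f8"
    compressed = False
    kind = None
    payload = ""
    for sub in bda:
        name = _localname(sub)
        if name == "cvParam":
            acc = sub.get("accession", "")
            if acc == _ACC_F64:
                dtype = "<f8"
            elif acc == _ACC_F32:
                dtype = "<f4"
            elif acc == _ACC_ZLIB:
                compressed = True
            elif acc == _ACC_MZ_ARRAY:
                kind = "mz"
            elif acc == _ACC_INT_ARRAY:
                kind = "intensity"
        elif name == "binary":
            payload = sub.text or ""
    data = base64.b64decode(payload)
    if compressed:
        data = zlib.decompress(data)
    return kind, np.frombuffer(data, dtype=dtype).astype(np.float64)


def _parse_spectrum(el) -> Spectrum:
    ms_level = 1
    polarity = "positive"
    rt = 0.0
    precursor = None
    profile = False
    for cv in _iter_cvparams(el):
        acc = cv.get("accession", "")
        parent = _localname(cv.getparent())
        if acc == _ACC_MS_LEVEL:
            ms_level = int(cv.get("value"))
        elif acc == _ACC_PROFILE:
            profile = True
        elif acc == _ACC_NEGATIVE:
            polarity = "negative"
        elif acc == _ACC_POSITIVE:
            polarity = "positive"
        elif acc == _ACC_SCAN_START:
            rt = float(cv.get("value"))
            unit = (cv.get("unitName") or "").lower()
            if "minute" in unit:
                rt *= 60.0
        elif acc == _ACC_SELECTED_MZ and parent == "selectedIon":
            precursor = float(cv.get("value"))
    if profile:
        raise UnsupportedDataError(
            "profile-mode spectra are not supported; centroid the data first"
        )
    mz = np.empty(0)
    inten = np.empty(0)
    for sub in el.iter():
        if _localname(sub) == "binaryDataArray":
            kind, arr = _decode_binary_array(sub)
            if kind == "mz":
                mz = arr
            elif kind == "intensity":
                inten = arr
    if len(mz) and not np.all(np.diff(mz) >= 0):
        order = np.argsort(mz, kind="stable")
        mz, inten = mz[order], inten[order]
    if ms_level == 2 and precursor is None:
        raise ValueError("MS2 spectrum without a selected ion m/z")
    return Spectrum(
        rt=rt,
        ms_level=ms_level,
        polarity=polarity,
        mz=mz,
        intensity=inten,
        precursor_mz=precursor if ms_level == 2 else None,
    )


def read_mzml(path) -> Run:
    """Read a centroided mzML file into a :class:`Run` (streaming).

    Raises :class:`UnsupportedDataError` on profile-mode spectra and
    ``lxml.etree.XMLSyntaxError`` on malformed XML.  RTs recorded in
    minutes are converted to seconds.
    """
    spectra: List[Spectrum] = []
    for _event, el in etree.iterparse(str(path), events=("end",)):
        if _localname(el) == "spectrum":
            spectra.append(_parse_spectrum(el))
            el.clear(keep_tail=True)
    run = Run(spectra=spectra)
    run.validate()
    return run


def _cv(accession: str, name: str, value: str = "", extra: str = "") -> str:
    return (
        f'<cvParam cvRef="MS" accession="{accession}" name="{name}" '
        f'value="{value}"{extra}/>'
    )


_SECOND_UNIT = ' unitCvRef="UO" unitAccession="UO:0000010" unitName="second"'
_MZ_UNIT = ' unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"'


def _encode(array: np.ndarray, dtype: str) -> str:
    data = np.asarray(array, dtype=dtype).tobytes()
    return base64.b64encode(data).decode("ascii")


def _spectrum_xml(spec: Spectrum, index: int) -> str:
    sid = f"scan={index + 1}"
    mz_b64 = _encode(spec.mz, "<f8")
    int_b64 = _encode(spec.intensity, "<f4")
    pol = (
        _cv("MS:1000129", "negative scan")
        if spec.polarity == "negative"
        else _cv("MS:1000130", "positive scan")
    )
    kind = (
        _cv("MS:1000579", "MS1 spectrum")
        if spec.ms_level == 1
        else _cv("MS:1000580", "MSn spectrum")
    )
    parts = [
        f'<spectrum index="{index}" id="{sid}" defaultArrayLength="{len(spec.mz)}">',
        _cv("MS:1000511", "ms level", str(spec.ms_level)),
        kind,
        _cv("MS:1000127", "centroid spectrum"),
        pol,
        '<scanList count="1">',
        _cv("MS:1000795", "no combination"),
        "<scan>",
        _cv("MS:1000016", "scan start time", repr(float(spec.rt)), _SECOND_UNIT),
        "</scan>",
        "</scanList>",
    ]
    if spec.ms_level == 2:
        parts += [
            '<precursorList count="1">',
            "<precursor>",
            '<selectedIonList count="1">',
            "<selectedIon>",
            _cv(
                "MS:1000744",
                "selected ion m/z",
                repr(float(spec.precursor_mz)),
                _MZ_UNIT,
            ),
            "</selectedIon>",
            "</selectedIonList>",
            "<activation/>",
            "</precursor>",
            "</precursorList>",
        ]
    parts += [
        '<binaryDataArrayList count="2">',
        f'<binaryDataArray encodedLength="{len(mz_b64)}">',
        _cv("MS:1000523", "64-bit float"),
        _cv("MS:1000576", "no compression"),
        _cv("MS:1000514", "m/z array", "", _MZ_UNIT),
        f"<binary>{mz_b64}</binary>",
        "</binaryDataArray>",
        f'<binaryDataArray encodedLength="{len(int_b64)}">',
        _cv("MS:1000521", "32-bit float"),
        _cv("MS:1000576", "no compression"),
        _cv(
            "MS:1000515",
            "intensity array",
            "",
            ' unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"',
        ),
        f"<binary>{int_b64}</binary>",
        "</binaryDataArray>",
        "</binaryDataArrayList>",
        "</spectrum>",
    ]
    return "".join(parts)


_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<indexedmzML xmlns="http://psi.hupo.org/ms/mzml" xmlns:xsi="http://www.w3.org/2001/XMLSchema-instance" xsi:schemaLocation="http://psi.hupo.org/ms/mzml http://psidev.info/files/ms/mzML/xsd/mzML1.1.2_idx.xsd">
<mzML xmlns="http://psi.hupo.org/ms/mzml" id="myfrquant_run" version="1.1.0">
<cvList count="2">
<cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
<cv id="UO" fullName="Unit Ontology" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>
</cvList>
<fileDescription>
<fileContent>
<cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
</fileContent>
</fileDescription>
<softwareList count="1">
<software id="myfrquant" version="0.1.0">
<cvParam cvRef="MS" accession="MS:1000799" name="custom unreleased software tool" value="myfrquant"/>
</software>
</softwareList>
<instrumentConfigurationList count="1">
<instrumentConfiguration id="IC1">
<cvParam cvRef="MS" accession="MS:1000031" name="instrument model" value=""/>
</instrumentConfiguration>
</instrumentConfigurationList>
<dataProcessingList count="1">
<dataProcessing id="DP1">
<processingMethod order="1" softwareRef="myfrquant">
<cvParam cvRef="MS" accession="MS:1000544" name="Conversion to mzML" value=""/>
</processingMethod>
</dataProcessing>
</dataProcessingList>
<run id="run1" defaultInstrumentConfigurationRef="IC1">
"""


def write_mzml(run: Run, path) -> None:
    """Write a :class:`Run` as indexed mzML (PSI standard layout).

    m/z arrays are encoded as uncompressed little-endian 64-bit floats (so
    they round-trip bit-exactly); intensities as 32-bit floats.  Output is a
    pure function of the run contents — no timestamps — so identical runs
    produce byte-identical files.
    """
    run.validate()
    buf = bytearray()
    buf += _HEADER.encode("utf-8")
    buf += (
        f'<spectrumList count="{len(run.spectra)}" '
        f'defaultDataProcessingRef="DP1">\n'
    ).encode("utf-8")
    offsets = []
    for i, spec in enumerate(run.spectra):
        offsets.append((f"scan={i + 1}", len(buf)))
        buf += _spectrum_xml(spec, i).encode("utf-8")
        buf += b"\n"
    buf += b"</spectrumList>\n</run>\n</mzML>\n"
    index_offset = len(buf)
    buf += b'<indexList count="1">\n<index name="spectrum">\n'
    for sid, off in offsets:
        buf += f'<offset idRef="{sid}">{off}</offset>\n'.encode("utf-8")
    buf += b"</index>\n</indexList>\n"
    buf += f"<indexListOffset>{index_offset}</indexListOffset>\n".encode("utf-8")
    buf += b"<fileChecksum>"
    sha1 = hashlib.sha1(bytes(buf)).hexdigest()
    buf += f"{sha1}</fileChecksum>\n</indexedmzML>\n".encode("utf-8")
    with open(path, "wb") as fh:
        fh.write(bytes(buf))


# ---------------------------------------------------------------------------
# Feature tables

#: Required TSV columns, in order.  ``monoisotopic`` (0/1) is an optional
#: extra written by this package; readers accept tables without it.
FEATURE_COLUMNS = [
    "feature_id",
    "mz",
    "charge",
    "rt_start",
    "rt_apex",
    "rt_end",
    "area",
    "apex_intensity",
]


def write_feature_table(features, path) -> None:
    """Write features as a TSV with the standard column set (UTF-8).

    A blank ``charge`` cell means unannotated.
    """
    rows = []
    for f in features:
        rows.append(
            {
                "feature_id": f.feature_id,
                "mz": f.mz,
                "charge": "" if f.charge is None else int(f.charge),
                "rt_start": f.rt_start,
                "rt_apex": f.rt_apex,
                "rt_end": f.rt_end,
                "area": f.area,
                "apex_intensity": f.apex_intensity,
                "monoisotopic": int(bool(f.monoisotopic)),
            }
        )
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS + ["monoisotopic"])
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_feature_table(path):
    """Read a feature TSV back into a list of Features.

    Raises :class:`SchemaError` if a required column is missing.
    """
    from .features import Feature  # deferred: features imports this module

    df = pd.read_csv(path, sep="\t", encoding="utf-8")
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"feature table missing required columns: {missing}")
    out = []
    for row in df.itertuples(index=False):
        charge = getattr(row, "charge")
        charge = None if pd.isna(charge) else int(charge)
        mono = getattr(row, "monoisotopic", 1)
        mono = True if pd.isna(mono) else bool(int(mono))
        out.append(
            Feature(
                feature_id=int(row.feature_id),
                mz=float(row.mz),
                rt_start=float(row.rt_start),
                rt_apex=float(row.rt_apex),
                rt_end=float(row.rt_end),
                area=float(row.area),
                apex_intensity=float(row.apex_intensity),
                charge=charge,
                monoisotopic=mono,
            )
        )
    return out
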