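"""Shared fixtures: packaged library, probe, and a tiny generated mzML file."""

import base64
import struct

import pytest

from thioltrace.chemmass import default_probe
from thioltrace.formats import load_library


@pytest.fixture(scope="session")
def library():
    return load_library()


@pytest.fixture(scope="session")
def probe():
    return default_probe()


# -- minimal mzML document builder ----------------------------------------

def _b64(values):
    return base64.b64encode(struct.pack(f"<{len(values)}d", *values)).decode()


def _binary_xml(values, kind):
    if kind == "mz":
        acc = 'accession="MS:1000514" name="m/z array"'
    else:
        acc = 'accession="MS:1000515" name="intensity array"'
    data = _b64(values)
    return (
        f'<binaryDataArray encodedLength="{len(data)}">'
        '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>'
        '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>'
        f'<cvParam cvRef="MS" {acc} value=""/>'
        f"<binary>{data}</binary></binaryDataArray>"
    )


def mzml_spectrum(index, ms_level, rt_sec, mz, intensity, precursor=None):
    prec = ""
    if precursor is not None:
        prec = (
            '<precursorList count="1"><precursor>'
            '<selectedIonList count="1"><selectedIon>'
            f'<cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{precursor}"/>'
            "</selectedIon></selectedIonList></precursor></precursorList>"
        )
    return (
        f'<spectrum index="{index}" id="scan={index + 1}" defaultArrayLength="{len(mz)}">'
        f'<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{ms_level}"/>'
        '<scanList count="1"><scan>'
        f'<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt_sec}" unitName="second"/>'
        "</scan></scanList>"
        f"{prec}"
        f'<binaryDataArrayList count="2">{_binary_xml(mz, "mz")}{_binary_xml(intensity, "int")}</binaryDataArrayList>'
        "</spectrum>"
    )


def mzml_document(spectra_xml):
    return (
        '<?xml version="1.0" encoding="utf-8"?>'
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0"><run id="r1">'
        f'<spectrumList count="{len(spectra_xml)}">{"".join(spectra_xml)}</spectrumList>'
        "</run></mzML>"
    )


@pytest.fixture
def tiny_mzml(tmp_path):
    """3 MS1 + 2 MS2 spectra; one MS2 carries the reporter ion. RTs in seconds."""
    doc = mzml_document(
        [
            mzml_spectrum(0, 1, 6.0, [100.0, 200.0], [1.0, 2.0]),
            mzml_spectrum(1, 2, 60.0, [150.0, 406.1753], [100.0, 900.0], precursor=493.2073),
            mzml_spectrum(2, 1, 90.0, [120.0], [3.0]),
            mzml_spectrum(3, 2, 120.0, [300.0], [50.0], precursor=550.2288),
            mzml_spectrum(4, 1, 150.0, [130.0], [4.0]),
        ]
    )
    path = tmp_path / "tiny.mzML"
    path.write_text(doc)
    return path
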