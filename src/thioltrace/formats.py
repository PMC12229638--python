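"""Readers and writers for the formats the toolkit exchanges.

MS2 spectra are read from mzML or MGF through pyteomics (MS1 spectra and
spectra without a precursor are skipped, with a logged count); runs are
written back as MGF with m/z at 6 decimals.  Compound libraries, calibration,
recovery and cohort tables travel as UTF-8 comma-separated CSV with a header
row.  Retention times are minutes throughout; mzML scan times in seconds are
converted on read.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import base64
import struct
import zlib
import xml.etree.ElementTree as ET

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .chemmass import Formula, FormulaError
from .screening import CompoundRecord, Ms2Spectrum

logger = logging.getLogger("thioltrace")

__all__ = [
    "read_ms2",
    "write_mgf",
    "load_library",
    "packaged_library_path",
    "load_packaged_csv",
    "load_transitions",
]

_LIBRARY_COLUMNS = [
    "index", "rt_min", "charge", "mz", "formula", "adducts",
    "description", "in_serum", "in_csf",
]


class Ms2ReadError(IOError):
    """Malformed or unreadable MS2 input."""


def _detect_format(path: str | Path, fmt: str | None) -> str:
    if fmt:
        return fmt.lower()
    suffix = Path(path).suffix.lower()
    if suffix == ".mgf":
        return "mgf"
    if suffix == ".mzml":
        return "mzml"
    raise ValueError(f"cannot infer MS2 format from {path!r}; pass format=")


def read_ms2(path: str | Path, format: str | None = None) -> list[Ms2Spectrum]:
    """Read MS2 spectra from an mzML or MGF file.

    MS1 spectra are skipped; MS2 spectra lacking a precursor m/z are skipped
    and counted in a log message.  A file yielding zero MS2 spectra logs an
    explicit empty-run warning.  Parse failures raise :class:`Ms2ReadError`
    naming the file and the index of the offending spectrum.
    """
    path = Path(path)
    if not path.exists():
        raise Ms2ReadError(f"no such file: {path}")
    fmt = _detect_format(path, format)
    reader = _read_mgf if fmt == "mgf" else _read_mzml
    spectra, skipped = reader(path)
    if skipped:
        logger.info("%s: skipped %d spectra without a precursor m/z", path, skipped)
    if not spectra:
        logger.warning("%s: empty run (no MS2 spectra)", path)
    return spectra


def _read_mgf(path: Path):
    out, skipped = [], 0
    try:
        with _mgf.MGF(str(path)) as reader:
            for i, spec in enumerate(reader):
                params = spec.get("params", {})
                pepmass = params.get("pepmass")
                if not pepmass or pepmass[0] is None:
                    skipped += 1
                    continue
                rt_s = params.get("rtinseconds")
                rt_min = float(rt_s) / 60.0 if rt_s is not None else 0.0
                out.append(
                    Ms2Spectrum(
                        spectrum_id=str(params.get("title", f"scan={i}")),
                        precursor_mz=float(pepmass[0]),
                        retention_time=rt_min,
                        mz=spec["m/z array"],
                        intensity=spec["intensity array"],
                    )
                )
    except Exception as exc:  # noqa: BLE001 - re-raise with context
        if isinstance(exc, Ms2ReadError):
            raise
        raise Ms2ReadError(f"{path}: parse error at spectrum {len(out)}: {exc}") from exc
    return out, skipped


# -- minimal MS2-only mzML reader ----------------------------------------
# Reads centroided spectra: ms level, scan start time (minute/second aware),
# selected ion m/z, and base64 binary arrays (64/32-bit float, zlib or none).

_ACC_MS_LEVEL = "MS:1000511"
_ACC_SCAN_TIME = "MS:1000016"
_ACC_SELECTED_MZ = "MS:1000744"
_ACC_F64, _ACC_F32 = "MS:1000523", "MS:1000521"
_ACC_ZLIB, _ACC_NONE = "MS:1000574", "MS:1000576"
_ACC_MZ_ARRAY, _ACC_INT_ARRAY = "MS:1000514", "MS:1000515"


def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary_array(elem) -> tuple[str | None, np.ndarray]:
    kind, fmt, compressed = None, "d", False
    payload = ""
    for child in elem.iter():
        name = _localname(child.tag)
        if name == "cvParam":
            acc = child.get("accession", "")
            if acc == _ACC_MZ_ARRAY:
                kind = "mz"
            elif acc == _ACC_INT_ARRAY:
                kind = "intensity"
            elif acc == _ACC_F32:
                fmt = "f"
            elif acc == _ACC_ZLIB:
                compressed = True
        elif name == "binary":
            payload = child.text or ""
    raw = base64.b64decode(payload)
    if compressed:
        raw = zlib.decompress(raw)
    width = struct.calcsize(fmt)
    n = len(raw) // width
    return kind, np.array(struct.unpack(f"<{n}{fmt}", raw[: n * width]))


def _parse_mzml_spectrum(elem):
    ms_level, rt_min, precursor = None, 0.0, None
    arrays: dict[str, np.ndarray] = {}
    for child in elem.iter():
        name = _localname(child.tag)
        if name == "cvParam":
            acc = child.get("accession", "")
            if acc == _ACC_MS_LEVEL:
                ms_level = int(child.get("value"))
            elif acc == _ACC_SCAN_TIME:
                t = float(child.get("value"))
                unit = (child.get("unitName") or "minute").lower()
                rt_min = t / 60.0 if unit.startswith("second") else t
            elif acc == _ACC_SELECTED_MZ:
                precursor = float(child.get("value"))
    for bda in elem.iter():
        if _localname(bda.tag) == "binaryDataArray":
            kind, arr = _decode_binary_array(bda)
            if kind:
                arrays[kind] = arr
    return ms_level, rt_min, precursor, arrays


def _read_mzml(path: Path):
    out, skipped = [], 0
    index = -1
    try:
        for _, elem in ET.iterparse(str(path), events=("end",)):
            if _localname(elem.tag) != "spectrum":
                continue
            index += 1
            spec_id = elem.get("id", f"index={index}")
            ms_level, rt_min, precursor, arrays = _parse_mzml_spectrum(elem)
            elem.clear()
            if ms_level != 2:
                continue
            if precursor is None:
                skipped += 1
                continue
            out.append(
                Ms2Spectrum(
                    spectrum_id=str(spec_id),
                    precursor_mz=precursor,
                    retention_time=rt_min,
                    mz=arrays.get("mz", np.empty(0)),
                    intensity=arrays.get("intensity", np.empty(0)),
                )
            )
    except ET.ParseError as exc:
        raise Ms2ReadError(
            f"{path}: parse error at spectrum {index + 1}: {exc}"
        ) from exc
    except Exception as exc:  # noqa: BLE001
        raise Ms2ReadError(f"{path}: parse error at spectrum {index}: {exc}") from exc
    return out, skipped


def write_mgf(spectra: Iterable[Ms2Spectrum], path: str | Path) -> None:
    """Write spectra as MGF (m/z at 6 decimals; byte-stable for equal input)."""
    entries = []
    for s in spectra:
        entries.append(
            {
                "m/z array": s.mz,
                "intensity array": s.intensity,
                "params": {
                    "title": s.spectrum_id,
                    "pepmass": round(float(s.precursor_mz), 6),
                    "rtinseconds": round(s.retention_time * 60.0, 4),
                    "charge": f"{s.precursor_charge}+",
                },
            }
        )
    with open(path, "w") as fh:
        _mgf.write(entries, fh, fragment_format="%.6f %.6f", write_charges=False)


def packaged_library_path():
    """Path-like handle to the packaged 97-entry compound library."""
    return resources.files("thioltrace.data").joinpath("table4_library.csv")


def load_packaged_csv(name: str) -> pd.DataFrame:
    """Load one of the packaged CSV fixtures by file name."""
    text = resources.files("thioltrace.data").joinpath(name).read_text()
    from io import StringIO

    return pd.read_csv(StringIO(text))


def load_library(path: str | Path | None = None) -> list[CompoundRecord]:
    """Load a compound library CSV into validated records.

    Defaults to the packaged 97-entry library.  Formulas must be plain Hill
    notation; underscored markup (``C_6_H_12_...``) is rejected with guidance.
    Duplicate indices are rejected; multiple adducts are ';'-separated.
    """
    if path is None:
        df = load_packaged_csv("table4_library.csv")
        src = "<packaged table4_library.csv>"
    else:
        df = pd.read_csv(path)
        src = str(path)
    missing = [c for c in _LIBRARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{src}: missing required column(s): {missing}")
    if df["index"].duplicated().any():
        dups = df.loc[df["index"].duplicated(), "index"].tolist()
        raise ValueError(f"{src}: duplicate record indices: {dups}")
    records = []
    for row_no, r in enumerate(df.itertuples(), start=2):
        raw = str(r.formula)
        if "_" in raw:
            raise ValueError(
                f"{src} row {row_no}: formula {raw!r} uses underscore markup; "
                "use plain Hill notation (e.g. C6H12N2O4S)"
            )
        try:
            formula = Formula.parse(raw)
        except FormulaError as exc:
            raise ValueError(f"{src} row {row_no}: {exc}") from exc
        adducts = tuple(a.strip() for a in str(r.adducts).split(";") if a.strip())
        records.append(
            CompoundRecord(
                index=int(r.index),
                retention_time=float(r.rt_min) if pd.notna(r.rt_min) else None,
                charge=int(r.charge),
                mz=float(r.mz),
                formula=formula,
                adducts=adducts,
                description=str(r.description),
                in_serum=bool(r.in_serum),
                in_csf=bool(r.in_csf),
            )
        )
    return records


def load_transitions() -> pd.DataFrame:
    """The packaged monitored-transition list for the seven targeted thiols."""
    return load_packaged_csv("table1_transitions.csv")
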