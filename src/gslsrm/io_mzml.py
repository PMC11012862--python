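"""Minimal mzML chromatogram reader/writer.

Supports exactly what SRM work needs: a flat list of chromatograms, each
with a time array (minutes) and an intensity array, encoded as base64
binary data arrays (64- or 32-bit floats, zlib or uncompressed). This
is not a general mzML implementation — spectra are ignored.
"""

from __future__ import annotations

import base64
import struct
import zlib
from pathlib import Path
from typing import Iterable
from xml.etree import ElementTree as ET

import numpy as np

from .quant import SRMChromatogram

__all__ = ["read_mzml_chromatograms", "write_mzml_chromatograms"]

_NS = "http://psi.hupo.org/ms/mzml"

# PSI-MS controlled-vocabulary accessions
_CV_TIME_ARRAY = "MS:1000595"
_CV_INTENSITY_ARRAY = "MS:1000515"
_CV_64BIT = "MS:1000523"
_CV_32BIT = "MS:1000521"
_CV_ZLIB = "MS:1000574"
_CV_NO_COMPRESSION = "MS:1000576"
_CV_UNIT_MINUTE = "UO:0000031"
_CV_UNIT_SECOND = "UO:0000010"


def _decode_array(binary_elem: ET.Element) -> tuple[np.ndarray, dict[str, str]]:
    accessions: dict[str, str] = {}
    for cv in binary_elem.iter(f"{{{_NS}}}cvParam"):
        accessions[cv.get("accession", "")] = cv.get("unitAccession", "")
    raw_elem = binary_elem.find(f"{{{_NS}}}binary")
    raw = base64.b64decode(raw_elem.text or "")
    if _CV_ZLIB in accessions:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _CV_32BIT in accessions else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float), accessions


def read_mzml_chromatograms(path: str | Path) -> list[SRMChromatogram]:
    """Read all chromatograms from an mzML file; times converted to minutes."""
    tree = ET.parse(path)
    out = []
    for chrom in tree.iter(f"{{{_NS}}}chromatogram"):
        time = intensity = None
        for bda in chrom.iter(f"{{{_NS}}}binaryDataArray"):
            values, acc = _decode_array(bda)
            if _CV_TIME_ARRAY in acc:
                if acc[_CV_TIME_ARRAY] == _CV_UNIT_SECOND:
                    values = values / 60.0
                time = values
            elif _CV_INTENSITY_ARRAY in acc:
                intensity = values
        if time is None or intensity is None:
            raise ValueError(
                f"chromatogram {chrom.get('id')!r} lacks a time or intensity array"
            )
        out.append(
            SRMChromatogram(
                transition_id=chrom.get("id", ""), time=time, intensity=intensity
            )
        )
    if not out:
        raise ValueError(f"no chromatograms found in {path}")
    return out


def _binary_data_array(values: np.ndarray, kind_accession: str, kind_name: str,
                       unit: bool) -> ET.Element:
    encoded = base64.b64encode(
        struct.pack(f"<{values.size}d", *values.astype(float))
    ).decode("ascii")
    bda = ET.Element("binaryDataArray", encodedLength=str(len(encoded)))
    ET.SubElement(bda, "cvParam", cvRef="MS", accession=_CV_64BIT,
                  name="64-bit float")
    ET.SubElement(bda, "cvParam", cvRef="MS", accession=_CV_NO_COMPRESSION,
                  name="no compression")
    attrs = {"cvRef": "MS", "accession": kind_accession, "name": kind_name}
    if unit:
        attrs.update(unitCvRef="UO", unitAccession=_CV_UNIT_MINUTE, unitName="minute")
    ET.SubElement(bda, "cvParam", **attrs)
    binary = ET.SubElement(bda, "binary")
    binary.text = encoded
    return bda


def write_mzml_chromatograms(
    chromatograms: Iterable[SRMChromatogram], path: str | Path
) -> None:
    """Write chromatograms as a minimal standalone mzML document."""
    chromatograms = list(chromatograms)
    root = ET.Element("mzML", xmlns=_NS, version="1.1.0")
    run = ET.SubElement(root, "run", id="run0")
    clist = ET.SubElement(run, "chromatogramList",
                          count=str(len(chromatograms)), defaultDataProcessingRef="dp0")
    for i, chrom in enumerate(chromatograms):
        elem = ET.SubElement(
            clist, "chromatogram", index=str(i), id=chrom.transition_id,
            defaultArrayLength=str(chrom.time.size),
        )
        arrays = ET.SubElement(elem, "binaryDataArrayList", count="2")
        arrays.append(_binary_data_array(chrom.time, _CV_TIME_ARRAY, "time array", True))
        arrays.append(
            _binary_data_array(chrom.intensity, _CV_INTENSITY_ARRAY,
                               "intensity array", False)
        )
    ET.indent(root)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")
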