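"""Minimal mzML reading/writing for profile MS1 spectra.

Supports 32/64-bit float binary arrays, with or without zlib compression.
Only what the pipeline needs; not a general mzML implementation.
"""

from __future__ import annotations

import base64
import xml.etree.ElementTree as ET
import zlib
from pathlib import Path

import numpy as np

_NS = "http://psi.hupo.org/ms/mzml"

# controlled-vocabulary accessions
_ACC_MS_LEVEL = "MS:1000511"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_NONE = "MS:1000576"
_ACC_MZ = "MS:1000514"
_ACC_INTENSITY = "MS:1000515"


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_array(elem: ET.Element) -> tuple[str | None, np.ndarray]:
    dtype = np.float64
    compressed = False
    kind: str | None = None
    payload = b""
    for child in elem.iter():
        name = _local(child.tag)
        if name == "cvParam":
            acc = child.get("accession", "")
            if acc == _ACC_F32:
                dtype = np.float32
            elif acc == _ACC_F64:
                dtype = np.float64
            elif acc == _ACC_ZLIB:
                compressed = True
            elif acc == _ACC_MZ:
                kind = "mz"
            elif acc == _ACC_INTENSITY:
                kind = "intensity"
        elif name == "binary" and child.text:
            payload = base64.b64decode(child.text.strip())
    if compressed:
        payload = zlib.decompress(payload)
    return kind, np.frombuffer(payload, dtype=dtype).astype(np.float64)


def read_mzml(path: str | Path) -> list[tuple[np.ndarray, np.ndarray]]:
    """Return (mz, intensity) array pairs for every MS1 spectrum in the file."""
    scans: list[tuple[np.ndarray, np.ndarray]] = []
    for _, elem in ET.iterparse(str(path), events=("end",)):
        if _local(elem.tag) != "spectrum":
            continue
        ms_level = 1
        arrays: dict[str, np.ndarray] = {}
        for child in elem.iter():
            name = _local(child.tag)
            if name == "cvParam" and child.get("accession") == _ACC_MS_LEVEL:
                ms_level = int(child.get("value", "1"))
            elif name == "binaryDataArray":
                kind, values = _decode_array(child)
                if kind is not None:
                    arrays[kind] = values
        if ms_level == 1 and "mz" in arrays and "intensity" in arrays:
            scans.append((arrays["mz"], arrays["intensity"]))
        elem.clear()
    if not scans:
        raise ValueError(f"{path}: no MS1 spectra found")
    return scans


def write_mzml(
    path: str | Path, scans: list[tuple[np.ndarray, np.ndarray]]
) -> None:
    """Write MS1 scans as uncompressed 64-bit profile mzML."""

    def b64(arr: np.ndarray) -> str:
        return base64.b64encode(np.asarray(arr, dtype=np.float64).tobytes()).decode()

    lines = [
        '<?xml version="1.0" encoding="utf-8"?>',
        f'<mzML xmlns="{_NS}" version="1.1.0">',
        f'  <run id="run1" defaultInstrumentConfigurationRef="IC1">',
        f'    <spectrumList count="{len(scans)}">',
    ]
    for i, (mz, intensity) in enumerate(scans):
        lines += [
            f'      <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{len(mz)}">',
            f'        <cvParam cvRef="MS" accession="{_ACC_MS_LEVEL}" name="ms level" value="1"/>',
            '        <binaryDataArrayList count="2">',
        ]
        for kind_acc, kind_name, arr in (
            (_ACC_MZ, "m/z array", mz),
            (_ACC_INTENSITY, "intensity array", intensity),
        ):
            enc = b64(arr)
            lines += [
                f'          <binaryDataArray encodedLength="{len(enc)}">',
                f'            <cvParam cvRef="MS" accession="{_ACC_F64}" name="64-bit float"/>',
                f'            <cvParam cvRef="MS" accession="{_ACC_NONE}" name="no compression"/>',
                f'            <cvParam cvRef="MS" accession="{kind_acc}" name="{kind_name}"/>',
                f"            <binary>{enc}</binary>",
                "          </binaryDataArray>",
            ]
        lines += ["        </binaryDataArrayList>", "      </spectrum>"]
    lines += ["    </spectrumList>", "  </run>", "</mzML>", ""]
    Path(path).write_text("\n".join(lines))
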