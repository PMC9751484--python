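"""Minimal ENVI-dialect cube I/O.

Supports the classic ASCII ``.hdr`` + raw binary payload pair, band-sequential
(BSQ) interleave, little-endian, data types 4 (32-bit float) and 12 (unsigned
16-bit).  In memory a cube is ``(lines, samples, bands)``; on disk BSQ stores
band-major ``(bands, lines, samples)``.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

__all__ = ["write_envi", "read_envi"]

_DTYPE_CODES = {4: np.dtype("<f4"), 12: np.dtype("<u2")}
_CODE_FOR = {v: k for k, v in _DTYPE_CODES.items()}


def _payload_path(hdr_path: Path) -> Path:
    for ext in (".img", ".dat", ".raw", ""):
        cand = hdr_path.with_suffix(ext)
        if cand.exists() and cand != hdr_path:
            return cand
    return hdr_path.with_suffix(".img")


def write_envi(hdr_path, cube: np.ndarray, wavelengths, data_type: int = 4) -> None:
    """Write ``cube`` (lines, samples, bands) as an ENVI .hdr/.img pair."""
    hdr_path = Path(hdr_path)
    if cube.ndim != 3:
        raise ValueError("cube must be (lines, samples, bands)")
    if data_type not in _DTYPE_CODES:
        raise ValueError(f"unsupported ENVI data type {data_type}; use 4 or 12")
    wavelengths = np.asarray(wavelengths, dtype=float)
    lines, samples, bands = cube.shape
    if wavelengths.size != bands:
        raise ValueError("one wavelength per band required")
    dtype = _DTYPE_CODES[data_type]
    wl_block = ",\n ".join(f"{w:.6f}" for w in wavelengths)
    hdr = (
        "ENVI\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {data_type}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        "wavelength = {\n " + wl_block + "}\n"
    )
    hdr_path.write_text(hdr)
    payload = np.ascontiguousarray(cube.transpose(2, 0, 1)).astype(dtype)
    payload.tofile(hdr_path.with_suffix(".img"))


def _parse_header(text: str) -> dict:
    # collapse { ... } blocks onto one line before parsing key = value pairs
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields = {}
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        fields[key.strip().lower()] = val.strip()
    return fields


def read_envi(hdr_path):
    """Read an ENVI .hdr/.img pair -> (cube (lines, samples, bands), wavelengths, header dict)."""
    hdr_path = Path(hdr_path)
    fields = _parse_header(hdr_path.read_text())
    for req in ("samples", "lines", "bands", "data type", "interleave"):
        if req not in fields:
            raise ValueError(f"ENVI header missing required field '{req}'")
    if fields["interleave"].lower() != "bsq":
        raise ValueError(f"only bsq interleave supported, got {fields['interleave']!r}")
    if fields.get("byte order", "0").strip() not in ("0", ""):
        raise ValueError("only little-endian (byte order = 0) supported")
    samples = int(fields["samples"])
    lines = int(fields["lines"])
    bands = int(fields["bands"])
    code = int(fields["data type"])
    if code not in _DTYPE_CODES:
        raise ValueError(f"unsupported ENVI data type {code}; use 4 or 12")
    offset = int(fields.get("header offset", "0") or 0)
    raw = np.fromfile(_payload_path(hdr_path), dtype=_DTYPE_CODES[code], offset=offset)
    expected = samples * lines * bands
    if raw.size != expected:
        raise ValueError(f"payload holds {raw.size} values, header promises {expected}")
    cube = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    wavelengths = None
    if "wavelength" in fields:
        inner = fields["wavelength"].strip().lstrip("{").rstrip("}")
        wavelengths = np.array([float(t) for t in inner.replace(",", " ").split()])
        if wavelengths.size != bands:
            raise ValueError("wavelength list length does not match band count")
    return cube, wavelengths, fields
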