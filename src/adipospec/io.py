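"""File I/O: ENVI-style header+binary cubes, per-pixel CSV cubes, HDF5
containers, two-column spectrum CSVs and integer label maps.

The ENVI container is a plain-text ``.hdr`` next to a band-sequential
float64 little-endian ``.dat``; it is the lossless round-trip format.  The
CSV cube dialect is one row per pixel (``row, col, <wavenumber...>``) with
``# key = value`` comment lines carrying pixel size and modality, and is
tolerant of instrument-style decreasing wavenumber columns.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import h5py
import numpy as np

from .core import (
    FormatError,
    HyperspectralCube,
    Modality,
    Spectrum,
    WavenumberAxis,
)

__all__ = [
    "read_cube",
    "write_cube",
    "read_spectrum",
    "write_spectrum",
    "read_labels",
    "write_labels",
]

_FORMATS = ("envi", "csv", "hdf5")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".hdr", ".dat", ".envi", ""):
        return "envi"
    if suffix == ".csv":
        return "csv"
    if suffix in (".h5", ".hdf5", ".hdf"):
        return "hdf5"
    raise FormatError(f"cannot infer cube format from {path.name!r}")


def write_cube(cube: HyperspectralCube, path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise FormatError(f"unknown cube format {fmt!r}")
    if fmt == "envi":
        _write_envi(cube, path)
    elif fmt == "csv":
        _write_csv(cube, path)
    else:
        _write_hdf5(cube, path)


def read_cube(path, format: str | None = None) -> HyperspectralCube:
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise FormatError(f"unknown cube format {fmt!r}")
    if fmt == "envi":
        return _read_envi(path)
    if fmt == "csv":
        return _read_csv(path)
    return _read_hdf5(path)


# ---------------------------------------------------------------- ENVI-style

def _envi_base(path: Path) -> Path:
    if path.suffix.lower() in (".hdr", ".dat"):
        return path.with_suffix("")
    return path


def _write_envi(cube: HyperspectralCube, path: Path) -> None:
    base = _envi_base(path)
    wavelengths = ", ".join(f"{v:.17g}" for v in cube.axis.values)
    lines = [
        "ENVI",
        "description = {adipospec hyperspectral cube}",
        f"samples = {cube.width}",
        f"lines = {cube.height}",
        f"bands = {len(cube.axis)}",
        "header offset = 0",
        "file type = ENVI Standard",
        "data type = 5",
        "interleave = bsq",
        "byte order = 0",
        "wavelength units = cm-1",
        f"pixel size = {float(cube.pixel_size):.17g}",
        f"modality = {cube.modality.value}",
        f"metadata = {json.dumps(dict(cube.metadata))}",
        "wavelength = {" + wavelengths + "}",
    ]
    base.with_suffix(".hdr").write_text("\n".join(lines) + "\n")
    # BSQ: (bands, lines, samples)
    bsq = np.ascontiguousarray(np.moveaxis(cube.data, 2, 0), dtype="<f8")
    bsq.tofile(base.with_suffix(".dat"))


def _parse_envi_header(text: str) -> dict:
    # collapse {...} blocks onto single logical entries
    entries: dict[str, str] = {}
    buffer = ""
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line == "ENVI":
            continue
        buffer = f"{buffer} {line}" if buffer else line
        if buffer.count("{") > buffer.count("}"):
            continue
        if "=" in buffer:
            key, value = buffer.split("=", 1)
            entries[key.strip().lower()] = value.strip()
        buffer = ""
    return entries

def _require(entries: dict, key: str, path: Path) -> str:
    if key not in entries:
        raise FormatError(f"{path.name}: missing required header key {key!r}")
    return entries[key]


def _read_envi(path: Path) -> HyperspectralCube:
    base = _envi_base(path)
    hdr = base.with_suffix(".hdr")
    if not hdr.exists():
        raise FormatError(f"header file {hdr} not found")
    entries = _parse_envi_header(hdr.read_text())
    samples = int(_require(entries, "samples", hdr))
    lines = int(_require(entries, "lines", hdr))
    bands = int(_require(entries, "bands", hdr))
    pixel_size = float(_require(entries, "pixel size", hdr))
    modality = entries.get("modality", "raman")
    metadata = json.loads(entries.get("metadata", "{}"))
    wl_text = _require(entries, "wavelength", hdr).strip("{} ")
    wavelengths = np.array([float(v) for v in re.split(r"[,\s]+", wl_text) if v])
    if wavelengths.size != bands:
        raise FormatError(f"{hdr.name}: wavelength count does not match bands")
    axis, flipped = WavenumberAxis.from_any(wavelengths)
    raw = np.fromfile(base.with_suffix(".dat"), dtype="<f8")
    if raw.size != samples * lines * bands:
        raise FormatError(f"{base.name}.dat: size does not match header shape")
    data = np.moveaxis(raw.reshape(bands, lines, samples), 0, 2)
    if flipped:
        data = data[:, :, ::-1]
    return HyperspectralCube(axis, data.copy(), pixel_size, modality, metadata)


# ----------------------------------------------------------------- CSV cube

def _write_csv(cube: HyperspectralCube, path: Path) -> None:
    header = ",".join(["row", "col"] + [f"{v:.17g}" for v in cube.axis.values])
    with open(path, "w") as fh:
        fh.write(f"# pixel_size = {float(cube.pixel_size):.17g}\n")
        fh.write(f"# modality = {cube.modality.value}\n")
        fh.write(f"# metadata = {json.dumps(dict(cube.metadata))}\n")
        fh.write(header + "\n")
        flat = cube.flat()
        for idx in range(cube.n_pixels):
            r, c = divmod(idx, cube.width)
            row = ",".join(f"{v:.17g}" for v in flat[idx])
            fh.write(f"{r},{c},{row}\n")


def _read_csv(path: Path) -> HyperspectralCube:
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line.lstrip("# ").partition("=")
            meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        header = line.strip().split(",")
        if header[:2] != ["row", "col"]:
            raise FormatError(f"{path.name}: expected 'row,col' leading columns")
        fh.seek(pos)
        fh.readline()
        body = np.loadtxt(fh, delimiter=",", ndmin=2)
    if "pixel_size" not in meta:
        raise FormatError(f"{path.name}: missing required key 'pixel_size'")
    pixel_size = float(meta["pixel_size"])
    modality = meta.get("modality", "raman")
    metadata = json.loads(meta.get("metadata", "{}"))
    wavelengths = np.array([float(v) for v in header[2:]])
    axis, flipped = WavenumberAxis.from_any(wavelengths)
    rows = body[:, 0].astype(int)
    cols = body[:, 1].astype(int)
    height, width = rows.max() + 1, cols.max() + 1
    data = np.zeros((height, width, len(axis)))
    intensities = body[:, 2:]
    if flipped:
        intensities = intensities[:, ::-1]
    data[rows, cols] = intensities
    return HyperspectralCube(axis, data, pixel_size, modality, metadata)


# --------------------------------------------------------------------- HDF5

def _write_hdf5(cube: HyperspectralCube, path: Path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("wavenumbers", data=cube.axis.values)
        fh.create_dataset("data", data=cube.data)
        fh.attrs["pixel_size"] = cube.pixel_size
        fh.attrs["modality"] = cube.modality.value
        fh.attrs["metadata"] = json.dumps(dict(cube.metadata))


def _read_hdf5(path: Path) -> HyperspectralCube:
    with h5py.File(path, "r") as fh:
        if "pixel_size" not in fh.attrs:
            raise FormatError(f"{Path(path).name}: missing attribute 'pixel_size'")
        axis, flipped = WavenumberAxis.from_any(fh["wavenumbers"][()])
        data = fh["data"][()]
        if flipped:
            data = data[:, :, ::-1]
        return HyperspectralCube(
            axis,
            data,
            float(fh.attrs["pixel_size"]),
            str(fh.attrs.get("modality", "raman")),
            json.loads(fh.attrs.get("metadata", "{}")),
        )


# ---------------------------------------------------------- single spectrum

def write_spectrum(spectrum: Spectrum, path) -> None:
    """Two-column CSV (wavenumber, intensity) with a modality comment."""
    with open(path, "w") as fh:
        fh.write(f"# modality = {spectrum.modality.value}\n")
        fh.write("wavenumber,intensity\n")
        for wn, value in zip(spectrum.axis.values, spectrum.intensities):
            fh.write(f"{wn:.17g},{value:.17g}\n")


def read_spectrum(path, modality: str | None = None) -> Spectrum:
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line.lstrip("# ").partition("=")
            meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        if any(not c.isdigit() and c not in ".,-+e " for c in line.strip()):
            fh.readline()  # skip column header
        body = np.loadtxt(fh, delimiter=",", ndmin=2)
    axis, flipped = WavenumberAxis.from_any(body[:, 0])
    intensities = body[::-1, 1].copy() if flipped else body[:, 1]
    return Spectrum(axis, intensities,
                    Modality.coerce(modality or meta.get("modality", "raman")))


# --------------------------------------------------------------- label maps

def write_labels(labels: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(labels, dtype=int), fmt="%d", delimiter=",")


def read_labels(path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",", dtype=int, ndmin=2)
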