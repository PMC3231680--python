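"""Cube, band-set and report I/O.

Three interchangeable on-disk cube formats are supported:

``envi``
    A flat binary array (BSQ or BIL interleave, float32) beside a plain-text
    ``.hdr`` file; the ``wavelength`` header field (nm) is required.
``geotiff``
    One raster page per spectral band; the wavelength is stored in each
    page's description as JSON (``{"wavelength_nm": ...}``).
``csv``
    Long format with header ``pixel_row,pixel_col,wavelength_nm,reflectance``;
    pixels absent from the table are masked on load.

Nodata pixels are written as NaN (binary formats) or omitted (CSV).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import FormatError, MetadataError, UsageError
from .spectral import BandDefinition, BandSet, ReflectanceCube, SRFModel

__all__ = ["load_cube", "write_cube", "load_bandset_config", "CSV_COLUMNS"]

CSV_COLUMNS = ["pixel_row", "pixel_col", "wavelength_nm", "reflectance"]

_FORMATS = ("envi", "geotiff", "csv")


def _check_axis(wl: np.ndarray, where: str) -> np.ndarray:
    wl = np.asarray(wl, dtype=float)
    if wl.size == 0:
        raise MetadataError(f"{where}: no wavelength metadata found")
    if wl.size > 1 and not np.all(np.diff(wl) > 0):
        raise MetadataError(f"{where}: wavelengths are not strictly increasing")
    return wl


def load_cube(path, format: str) -> ReflectanceCube:
    """Read a reflectance cube; see the module docstring for the formats."""
    path = Path(path)
    if format not in _FORMATS:
        raise UsageError(f"unknown format {format!r}; expected one of {_FORMATS}")
    if not path.exists():
        raise FileNotFoundError(path)
    return {"envi": _load_envi, "geotiff": _load_geotiff, "csv": _load_csv}[format](path)


def write_cube(cube: ReflectanceCube, path, format: str) -> None:
    """Write a cube so that :func:`load_cube` recovers axis and values
    (float32 rounding)."""
    path = Path(path)
    if format not in _FORMATS:
        raise UsageError(f"unknown format {format!r}; expected one of {_FORMATS}")
    path.parent.mkdir(parents=True, exist_ok=True)
    {"envi": _write_envi, "geotiff": _write_geotiff, "csv": _write_csv}[format](cube, path)


# ---------------------------------------------------------------- ENVI

def _envi_header_path(path: Path) -> Path:
    sidecar = Path(str(path) + ".hdr")
    return sidecar if sidecar.exists() else path.with_suffix(".hdr")


def _parse_envi_header(text: str) -> dict:
    """Minimal ENVI header parser: `key = value` lines, {}-braced lists."""
    fields: dict[str, str] = {}
    # join brace-continued values onto one line
    lines, buf = [], ""
    for raw in text.splitlines():
        buf = f"{buf} {raw}".strip() if buf else raw.strip()
        if buf.count("{") > buf.count("}"):
            continue
        if buf:
            lines.append(buf)
        buf = ""
    for line in lines:
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def _load_envi(path: Path) -> ReflectanceCube:
    hdr_path = _envi_header_path(path)
    if not hdr_path.exists():
        raise MetadataError(f"no ENVI header found for {path}")
    fields = _parse_envi_header(hdr_path.read_text())
    try:
        lines = int(fields["lines"])
        samples = int(fields["samples"])
        bands = int(fields["bands"])
    except KeyError as exc:
        raise MetadataError(f"{hdr_path}: missing required header field {exc}") from exc
    if "wavelength" not in fields:
        raise MetadataError(f"{hdr_path}: missing 'wavelength' field")
    wl = _check_axis(
        [float(v) for v in fields["wavelength"].strip("{} ").split(",") if v.strip()],
        str(hdr_path),
    )
    if wl.size != bands:
        raise FormatError(
            f"{hdr_path}: {wl.size} wavelengths but {bands} bands declared"
        )
    dtype = {"4": np.float32, "5": np.float64}.get(fields.get("data type", "4"))
    if dtype is None:
        raise FormatError(f"{hdr_path}: unsupported ENVI data type")
    interleave = fields.get("interleave", "bsq").lower()
    raw = np.fromfile(path, dtype=dtype)
    if raw.size != lines * samples * bands:
        raise FormatError(
            f"{path}: expected {lines * samples * bands} values, found {raw.size}"
        )
    if interleave == "bsq":
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:
        raise FormatError(f"{hdr_path}: unsupported interleave {interleave!r}")
    return ReflectanceCube(wl, data.astype(float), meta={"source": str(path)})


def _write_envi(cube: ReflectanceCube, path: Path) -> None:
    data = cube.data.astype(np.float32).copy()
    data[cube.mask] = np.nan
    data.transpose(2, 0, 1).tofile(path)  # BSQ
    wl = ", ".join(f"{w:.6g}" for w in cube.wavelengths)
    header = (
        "ENVI\n"
        f"samples = {cube.n_cols}\n"
        f"lines = {cube.n_rows}\n"
        f"bands = {cube.n_bands}\n"
        "data type = 4\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = nm\n"
        f"wavelength = {{ {wl} }}\n"
    )
    path.with_suffix(".hdr").write_text(header)


# ------------------------------------------------------------- GeoTIFF

def _write_geotiff(cube: ReflectanceCube, path: Path) -> None:
    data = cube.data.astype(np.float32).copy()
    data[cube.mask] = np.nan
    with tifffile.TiffWriter(path) as tif:
        for i, wl in enumerate(cube.wavelengths):
            tif.write(
                data[:, :, i],
                description=json.dumps({"wavelength_nm": float(wl)}),
                contiguous=False,
            )


def _load_geotiff(path: Path) -> ReflectanceCube:
    pages_data, wavelengths = [], []
    with tifffile.TiffFile(path) as tif:
        for page in tif.pages:
            desc = page.description or ""
            try:
                wl = float(json.loads(desc)["wavelength_nm"])
            except (json.JSONDecodeError, KeyError, TypeError) as exc:
                raise MetadataError(
                    f"{path}: band page lacks a wavelength_nm description"
                ) from exc
            wavelengths.append(wl)
            pages_data.append(page.asarray())
    wl = _check_axis(wavelengths, str(path))
    data = np.stack(pages_data, axis=-1).astype(float)
    return ReflectanceCube(wl, data, meta={"source": str(path)})


# ----------------------------------------------------------------- CSV

def _write_csv(cube: ReflectanceCube, path: Path) -> None:
    rows, cols = np.nonzero(~cube.mask)
    n_wl = cube.n_bands
    df = pd.DataFrame(
        {
            "pixel_row": np.repeat(rows, n_wl),
            "pixel_col": np.repeat(cols, n_wl),
            "wavelength_nm": np.tile(cube.wavelengths, rows.size),
            "reflectance": cube.data[rows, cols].ravel(),
        }
    )
    df.to_csv(path, index=False, float_format="%.9g")


def _load_csv(path: Path) -> ReflectanceCube:
    df = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    if df.empty:
        # a written empty cube keeps no axis information; return a 0-pixel cube
        return ReflectanceCube(np.array([1.0]), np.empty((0, 0, 1)))
    wl = _check_axis(np.unique(df["wavelength_nm"].to_numpy()), str(path))
    n_rows = int(df["pixel_row"].max()) + 1
    n_cols = int(df["pixel_col"].max()) + 1
    data = np.full((n_rows, n_cols, wl.size), np.nan)
    wl_index = {w: i for i, w in enumerate(wl)}
    counts = np.zeros((n_rows, n_cols), dtype=int)
    r = df["pixel_row"].to_numpy(int)
    c = df["pixel_col"].to_numpy(int)
    k = np.array([wl_index[w] for w in df["wavelength_nm"].to_numpy()])
    data[r, c, k] = df["reflectance"].to_numpy(float)
    np.add.at(counts, (r, c), 1)
    partial = (counts > 0) & (counts < wl.size)
    if np.any(partial):
        raise FormatError(
            f"{path}: {int(partial.sum())} pixel(s) have incomplete spectra"
        )
    return ReflectanceCube(wl, data, meta={"source": str(path)})


# -------------------------------------------------------------- config

def load_bandset_config(path) -> tuple[BandSet, SRFModel]:
    """Load a band-set + SRF choice from YAML or JSON.

    Schema::

        bands: [{id: B4, center_nm: 665, width_nm: 30}, ...]
        srf: boxcar | gaussian      # optional, default boxcar
        name: my-sensor             # optional
    """
    path = Path(path)
    cfg = yaml.safe_load(path.read_text())
    if not isinstance(cfg, dict) or "bands" not in cfg:
        raise FormatError(f"{path}: config must be a mapping with a 'bands' list")
    bands = tuple(
        BandDefinition(str(b["id"]), float(b["center_nm"]), float(b["width_nm"]))
        for b in cfg["bands"]
    )
    return (
        BandSet(bands, name=str(cfg.get("name", path.stem))),
        SRFModel(cfg.get("srf", "boxcar")),
    )
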