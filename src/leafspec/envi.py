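"""Minimal ENVI band-sequential raster I/O and GeoJSON-style polygon files.

Covers exactly the subset of the ENVI format the pipeline produces and
consumes: band-sequential (BSQ) float32 little-endian data with an ASCII
``.hdr`` companion carrying image dimensions, band-center wavelengths and a
simple ``map info`` record (pixel size and origin).
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
from shapely.geometry import mapping, shape

__all__ = [
    "write_envi",
    "read_envi",
    "write_lai_raster",
    "read_lai_raster",
    "write_polygons",
    "read_polygons",
]

_DATA_TYPE_FLOAT32 = 4


def write_envi(
    path,
    data: np.ndarray,
    band_centers,
    pixel_size: float = 5.0,
    origin: tuple[float, float] = (0.0, 0.0),
    description: str = "leafspec hyperspectral cube",
) -> Path:
    """Write a (rows, cols, bands) array as BSQ float32 with an ASCII header.

    Returns the path of the binary file; the header gets a ``.hdr`` suffix.
    """
    data = np.asarray(data, dtype=np.float32)
    if data.ndim == 2:
        data = data[:, :, None]
    if data.ndim != 3:
        raise ValueError("data must be (rows, cols, bands)")
    band_centers = np.asarray(band_centers, dtype=float)
    if band_centers.size != data.shape[2]:
        raise ValueError("one band center required per band")

    path = Path(path)
    rows, cols, bands = data.shape
    # BSQ: all rows/cols of band 0, then band 1, ...
    np.ascontiguousarray(np.moveaxis(data, 2, 0)).tofile(path)

    wl = ", ".join(f"{w:.4f}" for w in band_centers)
    hdr = (
        "ENVI\n"
        f"description = {{{description}}}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DATA_TYPE_FLOAT32}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"map info = {{Arbitrary, 1, 1, {origin[0]}, {origin[1]}, "
        f"{pixel_size}, {pixel_size}}}\n"
        f"wavelength = {{{wl}}}\n"
    )
    path.with_suffix(path.suffix + ".hdr").write_text(hdr)
    return path


def _parse_header(text: str) -> dict:
    # collapse brace-delimited multi-line values before splitting into fields
    text = text.replace("\n", " \n")
    fields: dict[str, str] = {}
    for m in re.finditer(r"(\w[\w ]*?)\s*=\s*(\{[^}]*\}|[^\n]*)", text):
        fields[m.group(1).strip().lower()] = m.group(2).strip().strip("{}").strip()
    return fields

def read_envi(path) -> tuple[np.ndarray, np.ndarray, dict]:
    """Read a BSQ float32 ENVI raster; returns (data, band_centers, meta)."""
    path = Path(path)
    hdr_path = path.with_suffix(path.suffix + ".hdr")
    fields = _parse_header(hdr_path.read_text())
    if int(fields.get("data type", 0)) != _DATA_TYPE_FLOAT32:
        raise ValueError("only float32 (data type 4) rasters are supported")
    if fields.get("interleave", "bsq").lower() != "bsq":
        raise ValueError("only BSQ interleave is supported")
    rows = int(fields["lines"])
    cols = int(fields["samples"])
    bands = int(fields["bands"])
    raw = np.fromfile(path, dtype=np.float32)
    if raw.size != rows * cols * bands:
        raise ValueError("raster size does not match header dimensions")
    data = np.moveaxis(raw.reshape(bands, rows, cols), 0, 2).astype(float)

    wavelength = fields.get("wavelength", "")
    band_centers = (
        np.array([float(v) for v in wavelength.split(",")])
        if wavelength
        else np.arange(bands, dtype=float)
    )
    meta: dict = {}
    if "map info" in fields:
        parts = [p.strip() for p in fields["map info"].split(",")]
        meta["origin"] = (float(parts[3]), float(parts[4]))
        meta["pixel_size"] = float(parts[5])
    return data, band_centers, meta


def write_lai_raster(path, lai: np.ndarray, **kwargs) -> Path:
    """Single-band LAI raster (m² leaf per m² ground)."""
    return write_envi(path, np.asarray(lai, dtype=float)[:, :, None],
                      band_centers=[0.0], description="LAI", **kwargs)


def read_lai_raster(path) -> np.ndarray:
    data, _, _ = read_envi(path)
    return data[:, :, 0]


def write_polygons(path, stands) -> Path:
    """Write stand polygons as a GeoJSON FeatureCollection."""
    features = []
    for st in stands:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(st.polygon),
                "properties": {"species": st.species, "site": st.site},
            }
        )
    path = Path(path)
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features}))
    return path


def read_polygons(path):
    from .image_mapping import StandPolygon

    doc = json.loads(Path(path).read_text())
    stands = []
    for feat in doc["features"]:
        props = feat.get("properties", {})
        stands.append(
            StandPolygon(
                polygon=shape(feat["geometry"]),
                species=props.get("species", ""),
                site=props.get("site", ""),
            )
        )
    return stands
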