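"""Project leaf-derived NDSI proxies onto hyperspectral image cubes.

The canopy-scale workflow mirrors the leaf-scale one: pixel spectra are
brightness-normalised (each spectrum divided by its Euclidean norm, which
cancels per-pixel illumination/density scaling), sparse-canopy pixels are
removed with a leaf-area-index (LAI) mask, two-band normalized difference
indices (NDSI) linked to leaf traits are computed per pixel, and the proxy
maps are summarised per mono-specific vegetation stand and rendered as RGB
"bio-visualisation" composites.

Pixel geometry is a simple axis-aligned grid: pixel (row, col) has its
center at ``origin + (col + 0.5, row + 0.5) * pixel_size``; polygon
membership is decided by pixel-center containment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

__all__ = [
    "HyperspectralCube",
    "ProxyMap",
    "StandPolygon",
    "WavelengthUnavailableError",
    "vector_normalize",
    "apply_lai_mask",
    "map_ndsi",
    "rgb_composite",
    "stand_statistics",
]


class WavelengthUnavailableError(ValueError):
    """No image band lies within tolerance of a requested wavelength."""


@dataclass
class HyperspectralCube:
    """(rows, cols, bands) reflectance raster with band-center wavelengths.

    ``mask`` is True where a pixel is invalid / excluded.
    """

    data: np.ndarray
    band_centers: np.ndarray
    mask: np.ndarray = None
    pixel_size: float = 5.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.band_centers = np.asarray(self.band_centers, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be (rows, cols, bands)")
        if self.band_centers.size != self.data.shape[2]:
            raise ValueError("band_centers length must equal band count")
        if np.any(np.diff(self.band_centers) <= 0):
            raise ValueError("band centers must be strictly increasing")
        if self.mask is None:
            self.mask = np.zeros(self.data.shape[:2], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:2]:
                raise ValueError("mask shape must match raster rows x cols")
        if np.any(self.data[~self.mask] < 0):
            raise ValueError("unmasked reflectance must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate grids of pixel centers."""
        rows, cols = self.data.shape[:2]
        x = self.origin[0] + (np.arange(cols) + 0.5) * self.pixel_size
        y = self.origin[1] + (np.arange(rows) + 0.5) * self.pixel_size
        return np.meshgrid(x, y)


@dataclass
class ProxyMap:
    """Per-pixel NDSI values for one trait-linked band pair."""

    values: np.ndarray
    pair: tuple[float, float]
    trait_label: str = ""
    mask: np.ndarray = None
    pixel_size: float = 5.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        valid = self.values[~self.mask]
        if valid.size and (np.nanmin(valid) < -1 - 1e-9 or np.nanmax(valid) > 1 + 1e-9):
            raise ValueError("unmasked NDSI values must lie in [-1, 1]")


@dataclass(frozen=True)
class StandPolygon:
    """Mono-specific vegetation stand outline."""

    polygon: Polygon
    species: str
    site: str = ""

    def __post_init__(self) -> None:
        if self.polygon.is_empty or self.polygon.area <= 0:
            raise ValueError("stand polygon must be non-degenerate")


def vector_normalize(cube: HyperspectralCube) -> HyperspectralCube:
    """Divide every unmasked pixel spectrum by its Euclidean norm.

    Removes per-pixel brightness differences caused by canopy density and
    illumination, leaving only spectral shape.  Zero-norm pixels are masked.
    """
    if cube.data.size == 0:
        raise ValueError("empty cube")
    norms = np.sqrt(np.sum(cube.data**2, axis=2))
    zero = norms == 0
    safe = np.where(zero, 1.0, norms)
    data = cube.data / safe[:, :, None]
    return replace(cube, data=data, mask=cube.mask | zero)


def apply_lai_mask(
    cube: HyperspectralCube, lai: np.ndarray, threshold: float = 0.67
) -> HyperspectralCube:
    """Mask pixels whose LAI is strictly below ``threshold`` (m² m⁻²)."""
    lai = np.asarray(lai, dtype=float)
    if lai.shape != cube.data.shape[:2]:
        raise ValueError("LAI raster shape must match the cube")
    return replace(cube, mask=cube.mask | (lai < threshold))


def _nearest_band(cube: HyperspectralCube, wavelength: float, tolerance: float) -> int:
    idx = int(np.argmin(np.abs(cube.band_centers - wavelength)))
    if abs(cube.band_centers[idx] - wavelength) > tolerance:
        raise WavelengthUnavailableError(
            f"no band within {tolerance} nm of {wavelength} nm"
        )
    return idx


def map_ndsi(
    cube: HyperspectralCube,
    lambda_i: float,
    lambda_j: float,
    tolerance: float = 5.0,
    trait_label: str = "",
) -> ProxyMap:
    """Per-pixel NDSI (rho_i - rho_j)/(rho_i + rho_j) at the nearest bands."""
    bi = _nearest_band(cube, lambda_i, tolerance)
    bj = _nearest_band(cube, lambda_j, tolerance)
    ri, rj = cube.data[:, :, bi], cube.data[:, :, bj]
    denom = ri + rj
    bad = denom == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(bad, np.nan, (ri - rj) / np.where(bad, 1.0, denom))
    return ProxyMap(
        values=values,
        pair=(float(cube.band_centers[bi]), float(cube.band_centers[bj])),
        trait_label=trait_label,
        mask=cube.mask | bad,
        pixel_size=cube.pixel_size,
        origin=cube.origin,
    )


def rgb_composite(
    maps: tuple[ProxyMap, ProxyMap, ProxyMap],
    stretch: tuple[float, float] = (2.0, 98.0),
) -> np.ndarray:
    """Stack three proxy maps into an RGB image with a percentile stretch.

    Each channel is linearly rescaled between its ``stretch`` percentiles
    (computed over unmasked pixels) and clipped to [0, 1].  Pixels masked in
    any input map come out black.  A constant channel is rendered at 0.5.
    """
    if len(maps) != 3:
        raise ValueError("exactly three proxy maps are required")
    shapes = {m.values.shape for m in maps}
    if len(shapes) != 1:
        raise ValueError("proxy maps must be aligned (same shape)")
    combined_mask = np.zeros(maps[0].values.shape, dtype=bool)
    for m in maps:
        combined_mask |= m.mask
    rgb = np.zeros(maps[0].values.shape + (3,), dtype=float)
    for c, m in enumerate(maps):
        valid = m.values[~combined_mask]
        if valid.size == 0:
            continue
        lo, hi = np.nanpercentile(valid, stretch)
        if hi <= lo:
            warnings.warn(
                f"constant proxy map in channel {c}; rendering at 0.5",
                stacklevel=2,
            )
            channel = np.full_like(m.values, 0.5)
        else:
            channel = np.clip((m.values - lo) / (hi - lo), 0.0, 1.0)
        rgb[:, :, c] = np.where(combined_mask, 0.0, channel)
    return rgb


def stand_statistics(proxy: ProxyMap, stands) -> pd.DataFrame:
    """Box-plot statistics of proxy values inside each stand polygon.

    Returns one row per stand: pixel count, median, quartiles and whisker
    extremes (Tukey 1.5 x IQR rule).  Stands with no unmasked pixel are
    flagged ``empty`` with NaN statistics.
    """
    x, y = _proxy_pixel_centers(proxy)
    rows = []
    for st in stands:
        inside = shapely.contains_xy(st.polygon, x.ravel(), y.ravel()).reshape(x.shape)
        use = inside & ~proxy.mask & np.isfinite(proxy.values)
        vals = proxy.values[use]
        if vals.size == 0:
            rows.append(
                dict(species=st.species, site=st.site, n=0, empty=True,
                     median=np.nan, q1=np.nan, q3=np.nan,
                     whisker_lo=np.nan, whisker_hi=np.nan)
            )
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        lo = vals[vals >= q1 - 1.5 * iqr].min()
        hi = vals[vals <= q3 + 1.5 * iqr].max()
        rows.append(
            dict(species=st.species, site=st.site, n=int(vals.size), empty=False,
                 median=float(med), q1=float(q1), q3=float(q3),
                 whisker_lo=float(lo), whisker_hi=float(hi))
        )
    return pd.DataFrame(rows)


def _proxy_pixel_centers(proxy: ProxyMap) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = proxy.values.shape
    x = proxy.origin[0] + (np.arange(cols) + 0.5) * proxy.pixel_size
    y = proxy.origin[1] + (np.arange(rows) + 0.5) * proxy.pixel_size
    return np.meshgrid(x, y)
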