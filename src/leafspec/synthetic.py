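"""Synthetic macrophyte leaf spectra, trait tables, light curves and scenes.

The generator emulates the statistical structure of a multi-species aquatic
macrophyte leaf dataset: six species groups with species-specific trait
means and intraspecific coefficients of variation; leaf reflectance over
400-2500 nm (987 bands by default) produced by a Beer-Lambert-style forward
model in which pigments imprint visible absorption features, leaf water
imprints SWIR features scaled by water mass per area, and dry matter
imprints SWIR features scaled by LMA; chlorophyll-fluorescence light
response curves; and small hyperspectral scenes with stand polygons and a
companion LAI raster.

Photophysiological traits (alpha, ETR_max, Fv/Fm, qP, qN) are drawn with a
deliberately weak, configurable coupling to the pigment pool that actually
shapes the spectrum, so that reflectance-based models recover structural and
pigment traits well but photophysiology only poorly - the qualitative regime
observed in field leaf spectroscopy of these species.

All draws go through one `numpy.random.Generator` seeded from the config, so
identical configs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .image_mapping import HyperspectralCube, StandPolygon
from .library import SpectralLibrary

__all__ = [
    "SpeciesSpec",
    "LibraryConfig",
    "SceneConfig",
    "default_species",
    "default_wavelength_grid",
    "generate_trait_table",
    "simulate_leaf_spectrum",
    "generate_library",
    "generate_light_curve",
    "generate_image_cube",
    "default_par_steps",
]

#: traits drawn on a log scale (strictly positive)
_LOGNORMAL_TRAITS = ("chl_a", "car", "lma", "alpha", "etr_max")
#: traits bounded in (0, 1), drawn on a logit scale
_LOGIT_TRAITS = ("dmc", "fv_fm", "qp", "qn")
_PHOTO_TRAITS = ("alpha", "etr_max", "fv_fm", "qp", "qn")

#: correlation between the carotenoid pool and the chlorophyll pool
_PIGMENT_POOL_COUPLING = 0.5


@dataclass(frozen=True)
class SpeciesSpec:
    """Trait means and intraspecific CVs of one species group.

    ``trait_means`` must provide chl_a, car (µg cm⁻²), ca_cb (dimensionless
    chlorophyll a/b ratio, from which chl_b is derived), dmc (g g⁻¹),
    lma (g m⁻²), alpha, etr_max (µmol m⁻² s⁻¹), fv_fm, qp, qn.
    ``photophysiology_coupling`` in [0, 1] sets how strongly the
    photophysiological traits track the chlorophyll pool.
    """

    name: str
    trait_means: dict
    trait_cvs: dict
    photophysiology_coupling: float = 0.3

    def __post_init__(self) -> None:
        m = self.trait_means
        if not (0.0 < m["dmc"] < 1.0):
            raise ValueError("DMC mean must lie in (0, 1)")
        for t in _LOGNORMAL_TRAITS + ("ca_cb",):
            if m[t] <= 0:
                raise ValueError(f"mean of {t} must be positive")
        for t in ("fv_fm", "qp", "qn"):
            if not (0.0 < m[t] < 1.0):
                raise ValueError(f"mean of {t} must lie in (0, 1)")
        if any(cv < 0 for cv in self.trait_cvs.values()):
            raise ValueError("CVs must be non-negative")
        if not (0.0 <= self.photophysiology_coupling <= 1.0):
            raise ValueError("photophysiology_coupling must lie in [0, 1]")

    def cv(self, trait: str) -> float:
        return float(self.trait_cvs.get(trait, 0.0))


def default_species() -> list[SpeciesSpec]:
    """Six macrophyte species groups with literature-plausible trait means.

    Intraspecific CVs follow the pattern observed at peak of growth in
    floating/emergent macrophyte communities (ETR_max and I_k most variable,
    Fv/Fm least; structural traits most variable in water chestnut).
    """
    # name: (chl_a, car, ca_cb, dmc, lma, alpha, etr_max, fv_fm, qp, qn)
    means = {
        "Ludwigia hexapetala": (42.0, 9.0, 3.3, 0.24, 42.0, 0.26, 85.0, 0.74, 0.62, 0.42),
        "Nelumbo nucifera": (35.0, 6.5, 3.1, 0.26, 45.0, 0.33, 60.0, 0.73, 0.55, 0.38),
        "Nuphar lutea": (33.0, 8.5, 2.5, 0.16, 78.0, 0.25, 55.0, 0.74, 0.48, 0.55),
        "Nymphaea alba": (30.0, 8.0, 2.4, 0.17, 72.0, 0.24, 52.0, 0.76, 0.45, 0.52),
        "Phragmites australis": (38.0, 8.8, 3.0, 0.33, 55.0, 0.27, 65.0, 0.78, 0.50, 0.50),
        "Trapa natans": (36.0, 6.8, 3.3, 0.21, 38.0, 0.26, 58.0, 0.72, 0.55, 0.40),
    }
    # alpha, etr_max, fv_fm, qn, qp, chl_a, car, ca_cb, dmc, lma
    cvs = {
        "Ludwigia hexapetala": (0.134, 0.886, 0.060, 0.325, 0.111, 0.303, 0.243, 0.098, 0.160, 0.163),
        "Nelumbo nucifera": (0.139, 0.277, 0.046, 0.263, 0.194, 0.286, 0.299, 0.089, 0.203, 0.216),
        "Nuphar lutea": (0.149, 0.279, 0.064, 0.133, 0.242, 0.313, 0.307, 0.186, 0.086, 0.171),
        "Nymphaea alba": (0.202, 0.396, 0.029, 0.183, 0.378, 0.190, 0.293, 0.293, 0.136, 0.217),
        "Phragmites australis": (0.074, 0.172, 0.044, 0.072, 0.156, 0.200, 0.200, 0.100, 0.120, 0.180),
        "Trapa natans": (0.150, 0.318, 0.099, 0.302, 0.214, 0.196, 0.258, 0.098, 0.292, 0.433),
    }
    specs = []
    for name in means:
        ca, car, cacb, dmc, lma, al, em, fv, qp, qn = means[name]
        c_al, c_em, c_fv, c_qn, c_qp, c_ca, c_car, c_cacb, c_dmc, c_lma = cvs[name]
        specs.append(
            SpeciesSpec(
                name=name,
                trait_means=dict(
                    chl_a=ca, car=car, ca_cb=cacb, dmc=dmc, lma=lma,
                    alpha=al, etr_max=em, fv_fm=fv, qp=qp, qn=qn,
                ),
                trait_cvs=dict(
                    chl_a=c_ca, car=c_car, ca_cb=c_cacb, dmc=c_dmc, lma=c_lma,
                    alpha=c_al, etr_max=c_em, fv_fm=c_fv, qp=c_qp, qn=c_qn,
                ),
            )
        )
    return specs


def default_wavelength_grid(n_bands: int = 987,
                            lo: float = 400.0, hi: float = 2500.0) -> np.ndarray:
    return np.linspace(lo, hi, n_bands)


@dataclass(frozen=True)
class LibraryConfig:
    """Sampling design of a synthetic leaf spectral library."""

    species: tuple = field(default_factory=lambda: tuple(default_species()))
    n_per_species: int = 25
    wavelength_grid: np.ndarray = field(default_factory=default_wavelength_grid)
    noise_sd: float = 0.01
    structure_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        grid = np.asarray(self.wavelength_grid, dtype=float)
        object.__setattr__(self, "wavelength_grid", grid)
        object.__setattr__(self, "species", tuple(self.species))
        if self.n_per_species <= 0:
            raise ValueError("n_per_species must be positive")
        if self.noise_sd < 0 or self.structure_sd < 0:
            raise ValueError("noise levels must be non-negative")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if grid[0] < 400.0 - 1e-9 or grid[-1] > 2500.0 + 1e-9:
            raise ValueError("wavelength grid must lie within [400, 2500] nm")


# --------------------------------------------------------------------------
# trait marginals
# --------------------------------------------------------------------------

def _lognormal_from_z(z: np.ndarray, mean: float, cv: float) -> np.ndarray:
    """Log-normal with exact mean and CV, driven by standard-normal z."""
    if cv == 0:
        return np.full_like(z, mean, dtype=float)
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return np.exp(mu + np.sqrt(sigma2) * z)


# Gauss-Hermite rule for logit-normal moments (probabilists' weights folded in)
_GH_X, _GH_W = np.polynomial.hermite_e.hermegauss(64)
_GH_W = _GH_W / np.sqrt(2.0 * np.pi)


def _logitnormal_moments(mu: float, sigma: float) -> tuple[float, float]:
    v = expit(mu + sigma * _GH_X)
    m1 = float(np.dot(_GH_W, v))
    m2 = float(np.dot(_GH_W, v**2))
    return m1, np.sqrt(max(m2 - m1**2, 0.0))


@lru_cache(maxsize=512)
def _logitnormal_params(mean: float, cv: float) -> tuple[float, float]:
    """Moment-matched (mu, sigma) of a logit-normal with given mean and CV."""
    if cv == 0:
        return float(logit(mean)), 0.0
    target_sd = cv * mean

    def mu_for(sigma: float) -> float:
        return brentq(
            lambda mu: _logitnormal_moments(mu, sigma)[0] - mean, -30.0, 30.0
        )

    def sd_err(sigma: float) -> float:
        return _logitnormal_moments(mu_for(sigma), sigma)[1] - target_sd

    # sd is monotone increasing in sigma; bracket generously
    hi = 1.0
    while sd_err(hi) < 0 and hi < 64:
        hi *= 2.0
    if sd_err(hi) < 0:
        raise ValueError(f"CV {cv} unattainable for logit-normal mean {mean}")
    sigma = brentq(sd_err, 1e-12, hi)
    return float(mu_for(sigma)), float(sigma)


def _logitnormal_from_z(z: np.ndarray, mean: float, cv: float) -> np.ndarray:
    if cv == 0:
        return np.full_like(z, mean, dtype=float)
    mu, sigma = _logitnormal_params(round(mean, 12), round(cv, 12))
    return expit(mu + sigma * z)


def _draw_trait(z: np.ndarray, trait: str, mean: float, cv: float) -> np.ndarray:
    if trait in _LOGIT_TRAITS:
        return _logitnormal_from_z(z, mean, cv)
    return _lognormal_from_z(z, mean, cv)


# --------------------------------------------------------------------------
# trait table
# --------------------------------------------------------------------------

def generate_trait_table(config: LibraryConfig) -> pd.DataFrame:
    """One row per sample: species metadata plus all leaf traits.

    Chl-b is derived from Chl-a and a per-sample Ca/Cb ratio drawn around
    the species ratio; I_k is the exact ratio ETR_max/alpha; the
    photophysiological traits share a latent factor with the chlorophyll
    pool whose loading is the species' ``photophysiology_coupling``.
    """
    rng = np.random.default_rng(config.seed)
    frames = []
    sites = ("Lake Hidvegi", "Mantua lakes system", "Lake Varese")
    for si, sp in enumerate(config.species):
        n = config.n_per_species
        m, c = sp.trait_means, sp.cv

        z_chl = rng.standard_normal(n)
        chl_a = _lognormal_from_z(z_chl, m["chl_a"], c("chl_a"))
        ca_cb = _lognormal_from_z(rng.standard_normal(n), m["ca_cb"], c("ca_cb"))
        chl_b = chl_a / ca_cb

        cc = _PIGMENT_POOL_COUPLING
        z_car = cc * z_chl + np.sqrt(1 - cc**2) * rng.standard_normal(n)
        car = _lognormal_from_z(z_car, m["car"], c("car"))

        dmc = _draw_trait(rng.standard_normal(n), "dmc", m["dmc"], c("dmc"))
        lma = _lognormal_from_z(rng.standard_normal(n), m["lma"], c("lma"))

        pc = sp.photophysiology_coupling
        photo = {}
        for trait in _PHOTO_TRAITS:
            u = pc * z_chl + np.sqrt(1 - pc**2) * rng.standard_normal(n)
            photo[trait] = _draw_trait(u, trait, m[trait], c(trait))

        frames.append(
            pd.DataFrame(
                {
                    "species": sp.name,
                    "site": sites[si % len(sites)],
                    "date": "2014-07-15",
                    "chl_a": chl_a,
                    "chl_b": chl_b,
                    "car": car,
                    "ca_cb": ca_cb,
                    "chl_car": (chl_a + chl_b) / car,
                    "dmc": dmc,
                    "lma": lma,
                    "alpha": photo["alpha"],
                    "etr_max": photo["etr_max"],
                    "ik": photo["etr_max"] / photo["alpha"],
                    "fv_fm": photo["fv_fm"],
                    "qp": photo["qp"],
                    "qn": photo["qn"],
                },
                index=[f"S{si:02d}_{k:04d}" for k in range(n)],
            )
        )
    table = pd.concat(frames)
    table.index.name = "sample_id"
    return table


# --------------------------------------------------------------------------
# leaf reflectance forward model
# --------------------------------------------------------------------------

def _gauss(lam: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-(((lam - center) / width) ** 2))


def _structural_baseline(lam: np.ndarray) -> np.ndarray:
    """Smooth pigment-free reflectance: moderate VIS level, NIR plateau,
    gentle decline into the SWIR."""
    red_edge = expit((lam - 705.0) / 40.0)
    return 0.32 + 0.20 * red_edge - 0.06 * (lam - 400.0) / 2100.0


# specific absorption shapes; amplitudes per unit trait value
def _pigment_absorption(lam, chl_a, chl_b, car):
    a = chl_a * (
        0.040 * _gauss(lam, 430.0, 22.0)
        + 0.042 * _gauss(lam, 665.0, 22.0)
        + 0.012 * _gauss(lam, 710.0, 28.0)  # long-wavelength wing -> red edge
        + 0.008 * _gauss(lam, 540.0, 150.0)  # broad VIS continuum (package effect)
    )
    b = chl_b * (0.035 * _gauss(lam, 460.0, 20.0) + 0.030 * _gauss(lam, 645.0, 18.0))
    c = car * 0.050 * _gauss(lam, 480.0, 22.0)
    return a + b + c


def _water_absorption(lam, water_g_m2):
    shape = (
        0.0020 * _gauss(lam, 1200.0, 60.0)
        + 0.0080 * _gauss(lam, 1450.0, 55.0)
        + 0.0120 * _gauss(lam, 1940.0, 70.0)
    )
    return water_g_m2 * shape


def _dry_matter_absorption(lam, lma_g_m2):
    shape = (
        0.0050 * _gauss(lam, 1720.0, 50.0)
        + 0.0060 * _gauss(lam, 2100.0, 60.0)
        + 0.0070 * _gauss(lam, 2300.0, 55.0)
    )
    return lma_g_m2 * shape


def water_mass_per_area(lma: float, dmc: float) -> float:
    """Fresh minus dry mass per area (g m⁻²): LMA * (1/DMC - 1)."""
    return lma * (1.0 / dmc - 1.0)


def simulate_leaf_spectrum(
    traits,
    grid: np.ndarray,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
    structural_tilt: float = 0.0,
) -> np.ndarray:
    """Reflectance R(λ) = P(λ)·exp(−A_pig − A_wat − A_dm)·(1 + ε).

    ``traits`` is a mapping (or trait-table row) with chl_a, chl_b, car
    (µg cm⁻²), dmc (g g⁻¹) and lma (g m⁻²).  ``structural_tilt`` is a
    dimensionless per-leaf slope applied to the baseline (internal-scattering
    differences between leaves that are independent of the measured traits).
    ε is i.i.d. multiplicative Gaussian noise of standard deviation
    ``noise_sd``.  Output clipped to [0.001, 0.999].
    """
    lam = np.asarray(grid, dtype=float)
    chl_a, chl_b, car = float(traits["chl_a"]), float(traits["chl_b"]), float(traits["car"])
    dmc, lma = float(traits["dmc"]), float(traits["lma"])
    if not (0.0 < dmc < 1.0) or lma <= 0 or min(chl_a, chl_b, car) < 0:
        raise ValueError("traits out of physical range")

    absorption = (
        _pigment_absorption(lam, chl_a, chl_b, car)
        + _water_absorption(lam, water_mass_per_area(lma, dmc))
        + _dry_matter_absorption(lam, lma)
    )
    baseline = _structural_baseline(lam) * (
        1.0 + structural_tilt * (lam - 1000.0) / 1500.0
    )
    refl = baseline * np.exp(-absorption)
    if noise_sd > 0:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        refl = refl * (1.0 + noise_sd * gen.standard_normal(lam.size))
    return np.clip(refl, 0.001, 0.999)


def generate_library(config: LibraryConfig) -> SpectralLibrary:
    """Paired trait table and reflectance matrix; bit-reproducible by seed."""
    traits = generate_trait_table(config)
    rng = np.random.default_rng(config.seed + 1)
    tilts = config.structure_sd * rng.standard_normal(len(traits))
    refl = np.empty((len(traits), config.wavelength_grid.size))
    for i, (_, row) in enumerate(traits.iterrows()):
        refl[i] = simulate_leaf_spectrum(
            row, config.wavelength_grid, config.noise_sd, rng,
            structural_tilt=tilts[i],
        )
    return SpectralLibrary(
        wavelengths=config.wavelength_grid, reflectance=refl, traits=traits
    )


# --------------------------------------------------------------------------
# fluorescence light curves
# --------------------------------------------------------------------------

def default_par_steps(n: int = 11, lo: float = 5.0, hi: float = 787.0) -> np.ndarray:
    """Geometric PAR actinic-light ladder (µmol m⁻² s⁻¹), PAM-style."""
    return np.geomspace(lo, hi, n)


def generate_light_curve(
    alpha: float,
    etr_max: float,
    par_steps: np.ndarray | None = None,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
):
    """Noisy ETR light curve from the saturating-exponential model.

    ``noise_sd`` is relative to ``etr_max`` (additive Gaussian noise of
    standard deviation noise_sd * etr_max).  Returns a
    :class:`~leafspec.leaf_traits.LightResponseCurve`.
    """
    from .leaf_traits import LightResponseCurve, webb_model

    if alpha <= 0 or etr_max <= 0:
        raise ValueError("alpha and etr_max must be positive")
    par = default_par_steps() if par_steps is None else np.asarray(par_steps, float)
    etr = webb_model(par, alpha, etr_max)
    if noise_sd > 0:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        etr = etr + noise_sd * etr_max * gen.standard_normal(par.size)
    return LightResponseCurve(par=par, etr=etr)


# --------------------------------------------------------------------------
# image scenes
# --------------------------------------------------------------------------

def default_scene_bands(n: int = 98, lo: float = 425.0, hi: float = 905.0) -> np.ndarray:
    return np.linspace(lo, hi, n)


@dataclass(frozen=True)
class SceneConfig:
    """Layout of a synthetic hyperspectral scene with vegetation stands."""

    rows: int = 60
    cols: int = 60
    band_centers: np.ndarray = field(default_factory=default_scene_bands)
    stands: tuple = ()  # (shapely Polygon, species name) pairs
    background_lai: float = 0.3
    stand_lai: float = 2.0
    noise_sd: float = 0.01
    pixel_size: float = 5.0
    seed: int = 0
    species: tuple = field(default_factory=lambda: tuple(default_species()))

    def __post_init__(self) -> None:
        object.__setattr__(self, "band_centers",
                           np.asarray(self.band_centers, dtype=float))
        object.__setattr__(self, "stands", tuple(self.stands))
        object.__setattr__(self, "species", tuple(self.species))
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError("scene must have positive dimensions")
        if self.background_lai < 0 or self.stand_lai < 0:
            raise ValueError("LAI must be non-negative")
        xmax = self.cols * self.pixel_size
        ymax = self.rows * self.pixel_size
        for poly, _ in self.stands:
            x0, y0, x1, y1 = poly.bounds
            if x0 < 0 or y0 < 0 or x1 > xmax or y1 > ymax:
                raise ValueError("stand polygon outside raster extent")


def _background_spectrum(lam: np.ndarray) -> np.ndarray:
    """Dark water-like background, dimming toward the NIR."""
    return 0.012 + 0.05 * np.exp(-(lam - 400.0) / 250.0)


def generate_image_cube(scene: SceneConfig):
    """Synthesise a scene: cube, LAI raster, stand polygons and label map.

    Each stand pixel receives an independent trait draw from its species
    spec (one latent chlorophyll factor per pixel), simulated at the scene
    band grid; background pixels get a dark water-like spectrum and
    ``background_lai``.  Returns ``(cube, lai, stands, species_map)`` where
    ``species_map`` holds the species name per pixel ('' for background).
    """
    rng = np.random.default_rng(scene.seed)
    spec_by_name = {sp.name: sp for sp in scene.species}
    lam = scene.band_centers

    rows, cols = scene.rows, scene.cols
    x = (np.arange(cols) + 0.5) * scene.pixel_size
    y = (np.arange(rows) + 0.5) * scene.pixel_size
    xg, yg = np.meshgrid(x, y)

    import shapely

    data = np.empty((rows, cols, lam.size))
    noise = scene.noise_sd * rng.standard_normal(data.shape)
    data[:] = _background_spectrum(lam)[None, None, :]
    species_map = np.full((rows, cols), "", dtype=object)
    lai = np.full((rows, cols), float(scene.background_lai))

    stand_objs = []
    for k, (poly, name) in enumerate(scene.stands):
        if name not in spec_by_name:
            raise KeyError(f"unknown species {name!r} in scene")
        sp = spec_by_name[name]
        inside = shapely.contains_xy(poly, xg.ravel(), yg.ravel()).reshape(rows, cols)
        idx = np.argwhere(inside)
        cfg = LibraryConfig(
            species=(sp,),
            n_per_species=max(len(idx), 1),
            wavelength_grid=lam,
            noise_sd=0.0,
            seed=int(rng.integers(2**31 - 1)),
        )
        traits = generate_trait_table(cfg)
        for (r, c), (_, trow) in zip(idx, traits.iterrows()):
            data[r, c] = simulate_leaf_spectrum(trow, lam, noise_sd=0.0)
        species_map[inside] = name
        lai[inside] = scene.stand_lai * (1.0 + 0.05 * rng.standard_normal(int(inside.sum())))
        stand_objs.append(StandPolygon(polygon=poly, species=name, site=f"stand_{k}"))

    data = np.clip(data * (1.0 + noise), 0.0, 1.0)
    cube = HyperspectralCube(
        data=data,
        band_centers=lam,
        pixel_size=scene.pixel_size,
        origin=(0.0, 0.0),
    )
    return cube, lai, stand_objs, species_map
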