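"""Photophysiological, pigment and structural leaf traits from raw measurements.

Photophysiology comes from pulse-amplitude-modulated (PAM) chlorophyll
fluorescence: the dark-adapted yields F0 and Fm give the maximal PSII
photochemical efficiency Fv/Fm, and an electron-transport-rate (ETR) light
response curve is fitted with a saturating-exponential (Webb-type) model

    ETR(PAR) = ETR_max * (1 - exp(-alpha * PAR / ETR_max))

whose parameters are the initial slope ``alpha`` (quantum-yield proxy), the
saturation rate ``ETR_max`` and the derived saturation irradiance
``I_k = ETR_max / alpha``.

Pigments (chlorophyll-a, chlorophyll-b, total carotenoids) are computed from
80 % acetone extract absorbances with the Lichtenthaler equations and
reported per unit leaf area (µg cm⁻²).  Structure is leaf dry matter content
(DMC, dry/fresh mass) and leaf mass per area (LMA, g m⁻²) from disc weights
and areas.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "FluorescenceRecord",
    "LightResponseCurve",
    "PhotoParams",
    "PigmentAssay",
    "StructuralAssay",
    "MeasurementError",
    "DegenerateCurveError",
    "compute_fvfm",
    "compute_etr",
    "fit_light_response",
    "compute_pigments",
    "pigment_ratios",
    "compute_structure",
]

CM2_PER_M2 = 1e4


class MeasurementError(ValueError):
    """Raised when raw measurements violate physical constraints."""


class DegenerateCurveError(MeasurementError):
    """Raised when a light response curve carries no usable signal."""


@dataclass(frozen=True)
class FluorescenceRecord:
    """Dark-adapted fluorescence yields plus the ETR-PAR points of one leaf."""

    f0: float
    fm: float
    etr_points: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.fm <= 0 or self.f0 < 0:
            raise MeasurementError("require Fm > 0 and F0 >= 0")
        for par, y in self.etr_points:
            if par < 0 or not (0.0 <= y <= 1.0):
                raise MeasurementError("PAR must be >= 0 and yields in [0, 1]")


@dataclass(frozen=True)
class LightResponseCurve:
    """ETR (µmol electrons m⁻² s⁻¹) as a function of PAR (µmol m⁻² s⁻¹)."""

    par: np.ndarray
    etr: np.ndarray

    def __post_init__(self) -> None:
        par = np.asarray(self.par, dtype=float)
        etr = np.asarray(self.etr, dtype=float)
        object.__setattr__(self, "par", par)
        object.__setattr__(self, "etr", etr)
        if par.ndim != 1 or par.shape != etr.shape:
            raise ValueError("par and etr must be 1-d arrays of equal length")
        if par.size < 4:
            raise ValueError("need at least 4 light-curve points")
        if np.any(np.diff(par) <= 0):
            raise ValueError("PAR steps must be strictly increasing")


@dataclass(frozen=True)
class PhotoParams:
    """Fitted photophysiology parameters of one leaf."""

    alpha: float
    etr_max: float
    ik: float
    fit_rmse: float
    fv_fm: float = np.nan
    qp: float = np.nan
    qn: float = np.nan
    converged: bool = True


@dataclass(frozen=True)
class PigmentAssay:
    """Pigment contents on a leaf-area basis (µg cm⁻²) with derived ratios."""

    chl_a: float
    chl_b: float
    car: float
    negative_flag: bool

    @property
    def ca_cb(self) -> float:
        return pigment_ratios(self)[0]

    @property
    def chl_car(self) -> float:
        return pigment_ratios(self)[1]


@dataclass(frozen=True)
class StructuralAssay:
    dmc: float
    lma: float


def compute_fvfm(record: FluorescenceRecord) -> float:
    """Maximal PSII photochemical efficiency (Fm - F0) / Fm.

    Raises :class:`MeasurementError` when Fm <= F0 (no variable fluorescence).
    """
    if record.fm <= record.f0:
        raise MeasurementError(
            f"Fm ({record.fm}) must exceed F0 ({record.f0}) for Fv/Fm"
        )
    return (record.fm - record.f0) / record.fm


def compute_etr(
    effective_yield: float,
    par: float,
    absorbance: float = 0.84,
    partition: float = 0.5,
) -> float:
    """Electron transport rate from effective PSII yield and incident PAR.

    ``absorbance`` is the assumed leaf absorptance (default 0.84) and
    ``partition`` the fraction of absorbed quanta reaching PSII (default 0.5,
    the usual PAM convention).
    """
    if not (0.0 <= effective_yield <= 1.0):
        raise MeasurementError("effective yield must lie in [0, 1]")
    if par < 0:
        raise MeasurementError("PAR must be non-negative")
    return effective_yield * par * absorbance * partition


def webb_model(par: np.ndarray, alpha: float, etr_max: float) -> np.ndarray:
    """Saturating-exponential ETR light-response model (no photoinhibition)."""
    par = np.asarray(par, dtype=float)
    return etr_max * (1.0 - np.exp(-alpha * par / etr_max))


def fit_light_response(
    curve: LightResponseCurve,
    max_iter: int = 500,
    xtol: float = 1e-8,
) -> PhotoParams:
    """Fit the Webb model to an ETR light curve by nonlinear least squares.

    Initialisation: ``alpha0`` from the through-origin slope of the first
    three points, ``etr_max0 = max(ETR)``.  ``ik`` is returned as the exact
    ratio ``etr_max / alpha``.  A fit that exhausts the iteration budget is
    returned with ``converged=False`` rather than raised.
    """
    par, etr = curve.par, curve.etr
    if np.allclose(etr, 0.0):
        raise DegenerateCurveError("all-zero ETR curve cannot be fitted")
    if np.allclose(etr, etr[0]):
        raise DegenerateCurveError("constant ETR curve cannot be fitted")

    head = slice(0, 3)
    denom = float(np.dot(par[head], par[head]))
    alpha0 = float(np.dot(par[head], etr[head]) / denom) if denom > 0 else 0.1
    alpha0 = max(alpha0, 1e-6)
    etr_max0 = max(float(np.max(etr)), 1e-6)

    def residuals(theta: np.ndarray) -> np.ndarray:
        return webb_model(par, theta[0], theta[1]) - etr

    sol = least_squares(
        residuals,
        x0=[alpha0, etr_max0],
        bounds=([1e-10, 1e-10], [np.inf, np.inf]),
        xtol=xtol,
        ftol=xtol,
        gtol=None,
        max_nfev=max_iter,
    )
    alpha, etr_max = float(sol.x[0]), float(sol.x[1])
    rmse = float(np.sqrt(np.mean(sol.fun**2)))
    return PhotoParams(
        alpha=alpha,
        etr_max=etr_max,
        ik=etr_max / alpha,
        fit_rmse=rmse,
        converged=bool(sol.success),
    )


# Lichtenthaler & Buschmann coefficients for 80 % acetone extracts,
# absorbances read at 663.2, 646.8 and 470 nm; concentrations in µg mL⁻¹.
def _lichtenthaler(a663_2: float, a646_8: float, a470: float) -> tuple[float, float, float]:
    chl_a = 12.25 * a663_2 - 2.79 * a646_8
    chl_b = 21.50 * a646_8 - 5.10 * a663_2
    car = (1000.0 * a470 - 1.82 * chl_a - 85.02 * chl_b) / 198.0
    return chl_a, chl_b, car


def compute_pigments(
    a663_2: float,
    a646_8: float,
    a470: float,
    extract_volume_ml: float,
    disc_area_cm2: float,
) -> PigmentAssay:
    """Pigment contents (µg cm⁻²) from extract absorbances.

    Negative concentrations (possible with degraded extracts) are NOT
    clamped; they are reported as-is with ``negative_flag`` set so the
    caller can screen the assay.
    """
    if min(a663_2, a646_8, a470) < 0:
        raise MeasurementError("absorbances must be non-negative")
    if extract_volume_ml <= 0 or disc_area_cm2 <= 0:
        raise MeasurementError("extract volume and disc area must be positive")
    chl_a, chl_b, car = _lichtenthaler(a663_2, a646_8, a470)
    scale = extract_volume_ml / disc_area_cm2  # µg mL⁻¹ → µg cm⁻²
    chl_a, chl_b, car = chl_a * scale, chl_b * scale, car * scale
    return PigmentAssay(
        chl_a=chl_a,
        chl_b=chl_b,
        car=car,
        negative_flag=bool(min(chl_a, chl_b, car) < 0),
    )


def pigment_ratios(assay: PigmentAssay) -> tuple[float, float]:
    """(Ca/Cb, Chl/Car) ratios; raises on zero denominators."""
    if assay.chl_b <= 0:
        raise MeasurementError("Ca/Cb undefined for non-positive Chl-b")
    if assay.car <= 0:
        raise MeasurementError("Chl/Car undefined for non-positive Car")
    return assay.chl_a / assay.chl_b, (assay.chl_a + assay.chl_b) / assay.car


def compute_structure(
    fresh_weight_g: float,
    dry_weight_g: float,
    disc_area_cm2: float,
) -> StructuralAssay:
    """DMC (dry/fresh, g g⁻¹) and LMA (dry mass per area, g m⁻²)."""
    if dry_weight_g <= 0:
        raise MeasurementError("dry weight must be positive")
    if dry_weight_g > fresh_weight_g:
        raise MeasurementError("dry weight cannot exceed fresh weight")
    if disc_area_cm2 <= 0:
        raise MeasurementError("disc area must be positive")
    return StructuralAssay(
        dmc=dry_weight_g / fresh_weight_g,
        lma=dry_weight_g / (disc_area_cm2 / CM2_PER_M2),
    )


def light_curve_from_yields(
    record: FluorescenceRecord,
    absorbance: float = 0.84,
    partition: float = 0.5,
) -> LightResponseCurve:
    """Build an ETR light curve from a record's (PAR, effective yield) pairs."""
    pts = sorted(record.etr_points)
    par = np.array([p for p, _ in pts], dtype=float)
    etr = np.array(
        [compute_etr(y, p, absorbance, partition) for p, y in pts], dtype=float
    )
    return LightResponseCurve(par=par, etr=etr)
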