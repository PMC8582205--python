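"""Exhaustive two-band NDSI search against leaf traits.

For every unordered pair of bands (i < j by wavelength) the normalized
difference spectral index

    NDSI_ij = (rho_i - rho_j) / (rho_i + rho_j)

is computed per sample and correlated (Pearson by default, Spearman
optionally) with a leaf trait across samples.  Two-sided p-values are
Bonferroni-adjusted over the number of pairs tested for that trait, and the
optimal pair is the significant pair with the highest squared correlation
R_cal² — the trait's best two-band spectral proxy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .library import SpectralLibrary

__all__ = [
    "NDSIMap",
    "compute_ndsi",
    "ndsi_grid",
    "adjust_p_bonferroni",
    "best_band_pair",
    "plot_ndsi_map",
]


def compute_ndsi(rho_i, rho_j):
    """(rho_i - rho_j) / (rho_i + rho_j); errors on a zero denominator."""
    rho_i = np.asarray(rho_i, dtype=float)
    rho_j = np.asarray(rho_j, dtype=float)
    denom = rho_i + rho_j
    if np.any(denom == 0):
        raise ZeroDivisionError("NDSI undefined where rho_i + rho_j == 0")
    return (rho_i - rho_j) / denom


def adjust_p_bonferroni(p, m: int):
    """Bonferroni family-wise adjustment min(1, p*m)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m < 1:
        raise ValueError("test count m must be >= 1")
    out = np.minimum(1.0, p * m)
    return float(out) if out.ndim == 0 else out


@dataclass
class NDSIMap:
    """Correlation of one trait with NDSI over all band pairs.

    Arrays are aligned over the upper-triangular pair enumeration
    ``(i, j), i < j`` of the wavelengths retained within the search range.
    ``r`` is signed for the (shorter, longer) orientation; entries for
    degenerate (constant) pairs are NaN.
    """

    wavelengths: np.ndarray
    i_idx: np.ndarray
    j_idx: np.ndarray
    r: np.ndarray
    p_adj: np.ndarray
    n: int
    trait: str
    method: str = "pearson"
    n_dropped: int = 0

    @property
    def r2(self) -> np.ndarray:
        return self.r**2

    @property
    def n_pairs(self) -> int:
        return self.r.size

    def pair_wavelengths(self, k: int) -> tuple[float, float]:
        return float(self.wavelengths[self.i_idx[k]]), float(self.wavelengths[self.j_idx[k]])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (lambda_i, lambda_j, r, r2, p_adj)."""
        return pd.DataFrame(
            {
                "lambda_i": self.wavelengths[self.i_idx],
                "lambda_j": self.wavelengths[self.j_idx],
                "r": self.r,
                "r2": self.r2,
                "p_adj": self.p_adj,
            }
        )

    def matrix(self, values: str = "r2") -> np.ndarray:
        """Square (band x band) matrix of r² (or r / p_adj), NaN off-search."""
        p = self.wavelengths.size
        out = np.full((p, p), np.nan)
        v = getattr(self, values) if values != "r2" else self.r2
        out[self.i_idx, self.j_idx] = v
        out[self.j_idx, self.i_idx] = v if values != "r" else -v
        return out


def _pearson_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for a correlation coefficient via the t transform."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.isclose(np.abs(r), 1.0), 0.0, p)


def ndsi_grid(
    library: SpectralLibrary,
    trait: str,
    wavelength_range: tuple[float, float] = (400.0, 2500.0),
    method: str = "pearson",
) -> NDSIMap:
    """Correlate every two-band NDSI with one trait across samples.

    Samples with a missing trait value are dropped (pairwise deletion,
    recorded in ``n_dropped``).  Constant NDSI columns yield NaN entries.
    The Bonferroni family is the set of pairs tested for this one trait.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    y_full = library.traits[trait].to_numpy(dtype=float)
    keep = np.isfinite(y_full)
    y = y_full[keep]
    if y.size < 3:
        raise ValueError("need at least 3 samples with a non-missing trait")
    if np.allclose(y, y[0]):
        raise ValueError(f"trait {trait!r} is constant; correlation undefined")

    lo, hi = wavelength_range
    band_sel = (library.wavelengths >= lo) & (library.wavelengths <= hi)
    wl = library.wavelengths[band_sel]
    refl = library.reflectance[np.ix_(keep, band_sel)]
    n, p = refl.shape
    if method == "spearman":
        y = stats.rankdata(y)

    yc = y - y.mean()
    ynorm = np.sqrt(np.dot(yc, yc))

    n_pairs = p * (p - 1) // 2
    i_idx = np.empty(n_pairs, dtype=np.int32)
    j_idx = np.empty(n_pairs, dtype=np.int32)
    r_all = np.empty(n_pairs)
    pos = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        for i in range(p - 1):
            a = refl[:, i][:, None]
            b = refl[:, i + 1 :]
            denom = a + b
            ndsi = np.where(denom == 0, np.nan, (a - b) / denom)
            if method == "spearman":
                ndsi = stats.rankdata(ndsi, axis=0)
            xc = ndsi - ndsi.mean(axis=0)
            xnorm = np.sqrt(np.einsum("ij,ij->j", xc, xc))
            r = (yc @ xc) / (ynorm * xnorm)
            m = b.shape[1]
            i_idx[pos : pos + m] = i
            j_idx[pos : pos + m] = np.arange(i + 1, p)
            r_all[pos : pos + m] = r
            pos += m

    p_raw = _pearson_p(r_all, n)
    p_adj = np.minimum(1.0, p_raw * n_pairs)
    return NDSIMap(
        wavelengths=wl,
        i_idx=i_idx,
        j_idx=j_idx,
        r=r_all,
        p_adj=p_adj,
        n=n,
        trait=trait,
        method=method,
        n_dropped=int((~keep).sum()),
    )


def best_band_pair(ndsi_map: NDSIMap, alpha: float = 0.01):
    """Significant pair with the highest R_cal²; None if none significant.

    Ties are broken toward the shorter first wavelength, then the shorter
    second wavelength.
    """
    if ndsi_map.n_pairs == 0:
        raise ValueError("empty NDSI map")
    r2 = ndsi_map.r2
    ok = np.isfinite(r2) & (ndsi_map.p_adj < alpha)
    if not np.any(ok):
        return None
    cand = np.flatnonzero(ok)
    best_r2 = r2[cand].max()
    at_max = cand[np.isclose(r2[cand], best_r2, rtol=0, atol=0)]
    # pair enumeration is lexicographic in (i, j), so the first hit wins ties
    k = int(at_max[0])
    return ndsi_map.pair_wavelengths(k), float(r2[k])


def plot_ndsi_map(ndsi_map: NDSIMap, alpha: float = 0.01, ax=None):
    """Two-band R_cal² heatmap (significant pairs only), as a correlogram."""
    import matplotlib.pyplot as plt

    mat = ndsi_map.matrix("r2")
    sig = ndsi_map.matrix("p_adj") < alpha
    mat = np.where(sig, mat, np.nan)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    wl = ndsi_map.wavelengths
    im = ax.imshow(
        mat,
        origin="lower",
        extent=(wl[0], wl[-1], wl[0], wl[-1]),
        vmin=0,
        vmax=1,
        cmap="viridis",
        aspect="auto",
    )
    ax.set_xlabel("wavelength j (nm)")
    ax.set_ylabel("wavelength i (nm)")
    ax.set_title(f"NDSI R$_{{cal}}^2$ vs {ndsi_map.trait} (n={ndsi_map.n})")
    plt.colorbar(im, ax=ax, label="R$_{cal}^2$")
    return ax
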