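"""Spectral library containers and their on-disk tabular formats.

A :class:`SpectralLibrary` pairs an ``N x P`` leaf reflectance matrix on a
common wavelength grid with a trait table (one row per leaf sample, keyed by
sample ID, carrying species/site/date metadata).  The on-disk format is
plain text: a wide tab-separated spectra file whose first column is the
wavelength in nm and whose remaining columns are samples, plus a trait CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Spectrum", "SpectralLibrary"]

METADATA_COLUMNS = ("species", "site", "date")


@dataclass(frozen=True)
class Spectrum:
    """One leaf reflectance spectrum."""

    wavelengths: np.ndarray
    reflectance: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        rf = np.asarray(self.reflectance, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "reflectance", rf)
        if wl.shape != rf.shape or wl.ndim != 1:
            raise ValueError("wavelengths and reflectance must be 1-d, same length")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any((rf < 0) | (rf > 1)):
            raise ValueError("reflectance must lie in [0, 1]")


@dataclass
class SpectralLibrary:
    """Reflectance matrix plus aligned trait table.

    ``reflectance`` is (n_samples, n_bands); ``traits`` is indexed by
    sample ID in the same row order as the reflectance matrix.
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    traits: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.reflectance.ndim != 2:
            raise ValueError("reflectance must be a 2-d (samples x bands) matrix")
        if self.reflectance.shape[1] != self.wavelengths.size:
            raise ValueError("band count mismatch between grid and matrix")
        if len(self.traits) != self.reflectance.shape[0]:
            raise ValueError("one trait row is required per spectrum")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_bands(self) -> int:
        return self.wavelengths.size

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.traits.index]

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(
            wavelengths=self.wavelengths,
            reflectance=self.reflectance[i],
            sample_id=str(self.traits.index[i]),
        )

    # ------------------------------------------------------------------ I/O
    def write(self, spectra_path, traits_path) -> None:
        """Write the wide spectra table (TSV) and the trait CSV."""
        wide = pd.DataFrame(
            self.reflectance.T,
            index=pd.Index(self.wavelengths, name="wavelength_nm"),
            columns=self.sample_ids,
        )
        wide.to_csv(spectra_path, sep="\t", float_format="%.6f")
        self.traits.to_csv(traits_path, index_label="sample_id")

    @classmethod
    def read(cls, spectra_path, traits_path) -> "SpectralLibrary":
        wide = pd.read_csv(spectra_path, sep="\t", index_col=0)
        traits = pd.read_csv(traits_path, index_col="sample_id")
        traits.index = traits.index.astype(str)
        ordered = traits.loc[[str(c) for c in wide.columns]]
        return cls(
            wavelengths=wide.index.to_numpy(dtype=float),
            reflectance=wide.to_numpy(dtype=float).T,
            traits=ordered,
        )
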