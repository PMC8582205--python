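import matplotlib

matplotlib.use("Agg")

import numpy as np
import pandas as pd
import pytest

from leafspec.library import SpectralLibrary
from leafspec.synthetic import LibraryConfig, generate_library


@pytest.fixture(scope="session")
def library150() -> SpectralLibrary:
    """Default synthetic library: 6 species x 25 samples, 987 bands, 1 % noise."""
    return generate_library(LibraryConfig(seed=42))


@pytest.fixture(scope="session")
def toy_library() -> SpectralLibrary:
    """Tiny 5-band, 10-sample library for brute-force oracle comparisons."""
    rng = np.random.default_rng(7)
    wavelengths = np.array([450.0, 550.0, 680.0, 1450.0, 2300.0])
    refl = rng.uniform(0.05, 0.6, size=(10, 5))
    traits = pd.DataFrame(
        {
            "species": ["sp1"] * 5 + ["sp2"] * 5,
            "trait": rng.normal(10.0, 3.0, size=10),
        },
        index=[f"T{i:02d}" for i in range(10)],
    )
    traits.index.name = "sample_id"
    return SpectralLibrary(wavelengths=wavelengths, reflectance=refl, traits=traits)
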