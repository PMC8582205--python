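"""Generate the synthetic leaf spectral library the later stages analyse.

Six macrophyte species x 25 leaves, 987-band reflectance (400-2500 nm) with
1 % measurement noise and per-leaf structural variability.  The full library
(spectra + trait table) goes to scratch/ (bulky); a compact per-species
trait summary goes to results/.
"""

from pathlib import Path

from leafspec.synthetic import LibraryConfig, generate_library

ROOT = Path(__file__).resolve().parents[1]

lib = generate_library(LibraryConfig(seed=42))
print(f"library: {lib.n_samples} samples x {lib.n_bands} bands "
      f"({lib.wavelengths[0]:.0f}-{lib.wavelengths[-1]:.0f} nm)")

out = ROOT / "scratch" / "library"
out.mkdir(parents=True, exist_ok=True)
lib.write(out / "spectra.tsv", out / "traits.csv")
print(f"wrote {out}/spectra.tsv and traits.csv")

summary = (
    lib.traits.groupby("species")[["chl_a", "chl_b", "car", "chl_car", "dmc",
                                   "lma", "alpha", "etr_max", "fv_fm", "qp", "qn"]]
    .agg(["mean", "std"])
    .round(3)
)
dest = ROOT / "results" / "trait_summary.csv"
dest.parent.mkdir(exist_ok=True)
summary.to_csv(dest)
print(f"per-species trait summary -> {dest}")
print(summary["chl_a"])
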