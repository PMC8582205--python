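"""Exhaustive two-band NDSI search for every leaf trait.

Correlates all 486,591 band-pair indices with each trait (Bonferroni-adjusted
Pearson), records the optimal significant pair per trait, and renders the
R_cal² correlograms.  Full maps are bulky and go to scratch/; the best-pair
table goes to results/.
"""

from pathlib import Path

import matplotlib.pyplot as plt
import pandas as pd

from leafspec.spectral_indices import best_band_pair, ndsi_grid, plot_ndsi_map
from leafspec.synthetic import LibraryConfig, generate_library

ROOT = Path(__file__).resolve().parents[1]
FIG = ROOT / "scratch" / "figures"
FIG.mkdir(parents=True, exist_ok=True)

TRAITS = ["alpha", "etr_max", "fv_fm", "qp", "qn",
          "chl_a", "chl_b", "car", "ca_cb", "chl_car", "dmc", "lma"]

lib = generate_library(LibraryConfig(seed=42))
rows, maps = [], {}
for trait in TRAITS:
    m = ndsi_grid(lib, trait)
    maps[trait] = m
    hit = best_band_pair(m, alpha=0.01)
    if hit is None:
        rows.append(dict(trait=trait, lambda_i=None, lambda_j=None,
                         r2_best=None, significant=False))
        print(f"{trait:8s}: no Bonferroni-significant pair")
        continue
    (li, lj), r2 = hit
    rows.append(dict(trait=trait, lambda_i=round(li, 1), lambda_j=round(lj, 1),
                     r2_best=round(r2, 3), significant=True))
    print(f"{trait:8s}: best NDSI_({li:.0f},{lj:.0f})  R_cal² = {r2:.3f}")

    ax = plot_ndsi_map(m, alpha=0.01)
    ax.figure.savefig(FIG / f"ndsi_map_{trait}.png", dpi=120)
    plt.close(ax.figure)

best = pd.DataFrame(rows).set_index("trait")
best.to_csv(ROOT / "results" / "ndsi_best_pairs.csv")
print(f"\nbest-pair table -> results/ndsi_best_pairs.csv; maps -> {FIG}")
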