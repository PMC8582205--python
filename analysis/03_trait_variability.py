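"""Inter- and intraspecific trait variability of the synthetic dataset.

Per-species CVs at peak of growth, Kruskal-Wallis omnibus tests with Dunn/BH
post-hoc comparisons per trait, and the trait correlation matrix used later
to prune redundant traits before PLSR modelling.
"""

from pathlib import Path

import pandas as pd

from leafspec.synthetic import LibraryConfig, generate_trait_table
from leafspec.variability import (
    GroupedTraits,
    cv_table,
    dunn_posthoc_bh,
    kruskal_wallis,
    trait_correlation_matrix,
)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
TRAITS = ["alpha", "etr_max", "ik", "fv_fm", "qn", "qp",
          "chl_a", "chl_b", "car", "ca_cb", "chl_car", "dmc", "lma"]

table = generate_trait_table(LibraryConfig(seed=42))

cvs = cv_table(table, TRAITS).round(3)
cvs.to_csv(RESULTS / "cv_table.csv")
print("per-species CV at peak of growth (extremes):")
print(cvs.agg(["min", "max"]).T)

rows = []
for trait in TRAITS:
    grouped = GroupedTraits.from_table(table, trait)
    h, p = kruskal_wallis(grouped)
    dunn = dunn_posthoc_bh(grouped)
    n_sig = int((dunn["p_adj"] < 0.05).sum())
    rows.append(dict(trait=trait, kw_h=h, kw_p=p,
                     dunn_pairs_sig=n_sig, dunn_pairs=len(dunn)))
tests = pd.DataFrame(rows).set_index("trait").round(6)
tests.to_csv(RESULTS / "kruskal_dunn.csv")
print("\nKruskal-Wallis across species (significant Dunn pairs of 15):")
print(tests)

r, p, stars = trait_correlation_matrix(table, TRAITS)
r.round(3).to_csv(RESULTS / "trait_correlations.csv")
print("\n|r| > 0.5 trait pairs (candidates for exclusion before PLSR):")
for i, t1 in enumerate(TRAITS):
    for t2 in TRAITS[i + 1:]:
        if abs(r.loc[t1, t2]) > 0.5:
            print(f"  {t1:8s} ~ {t2:8s} r = {r.loc[t1, t2]:+.2f} {stars.loc[t1, t2]}")
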