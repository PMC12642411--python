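#!/usr/bin/env python
"""Date the element family by LTR-LTR divergence and fit the distance
distribution with a Gaussian mixture.

Simulates a family of elements dominated by recent insertions (plus an older
minority), measures each element's 5'-3' LTR p-distance by global alignment,
fits a 1-D Gaussian mixture by EM with BIC model selection, and converts the
young component to an age with the 2*mu*T clock. A mixture mode at zero
distance is the signature of a currently or recently replicating family.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ervpop.ltr_dating import distance_to_age, fit_gmm, ltr_distance
from ervpop.synthetic_data import simulate_ltr_pairs

BASE = Path(__file__).resolve().parent.parent / "results"
MU = 1e-8

young = simulate_ltr_pairs(2000, MU, 600, 200, seed=31)
old = simulate_ltr_pairs(300_000, 1e-7, 600, 80, seed=32)
distances = np.array([ltr_distance(a, b) for a, b in young + old])
ages = [distance_to_age(d, MU) for d in distances[:200]]

fit = fit_gmm(distances, k_range=(1, 3), seed=0)
pd.DataFrame({"element": range(distances.size), "distance": distances}).to_csv(
    BASE / "ltr_distances.tsv", sep="\t", index=False
)
report = {
    "n_elements": int(distances.size),
    "k_selected_by_bic": fit.k,
    "weights": fit.weights.tolist(),
    "means": fit.means.tolist(),
    "variances": fit.variances.tolist(),
    "mode": fit.mode,
    "bic": fit.bic,
    "young_component_mean_age_gen": float(np.mean(ages)),
}
(BASE / "ltr_gmm_fit.json").write_text(json.dumps(report, indent=2) + "\n")
print(f"family of {distances.size} elements: BIC selects K={fit.k}, "
      f"mixture mode at distance {fit.mode:.5f} (zero => active family)")
print(f"young component: mean LTR distance "
      f"{distances[:200].mean():.2e} => clock age "
      f"{np.mean(ages):,.0f} generations (planted: 2,000)")
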