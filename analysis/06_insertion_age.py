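#!/usr/bin/env python
"""Grid-search insertion dating and the establishment-conditioned drift test.

Summarises the carrier haplotypes as per-window segregating sites, runs the
survival-conditioned Wright-Fisher grid search over candidate insertion
times, and then asks whether the observed trait frequency (25.4% of
individuals, allele frequency ~0.136) is higher than drift predicts
conditional on the insertion's establishment.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ervpop import io
from ervpop.insertion_inference import (
    establishment_frequency_test,
    grid_search_insertion_time,
    summarize_observed,
)

BASE = Path(__file__).resolve().parent.parent / "results"
DATA = BASE / "data"

hapset = io.read_hapset(DATA / "haplotypes.fa", DATA / "haplotype_labels.tsv")
demography = io.read_demography(DATA / "demography.json")
carriers = [s for s, n in zip(hapset.seqs, hapset.names)
            if hapset.labels[n] == "carrier"]
observed = summarize_observed(carriers, window=5000)
print(f"observed carrier summary: {observed[-1]:.0f} segregating sites "
      f"across {observed.size - 1} windows")

grid = list(range(500, 4001, 500))
result = grid_search_insertion_time(
    observed, demography, 1e-8, 50_000, len(carriers), grid,
    reps=200, window=5000, seed=2,
)
result.distances.to_csv(BASE / "grid_search_distances.tsv", sep="\t", index=False)
profile = pd.DataFrame({"T": result.grid, "mean_distance": result.mean_distance})
print(profile.round(3).to_string(index=False))
within = result.times_within(0.25 * result.mean_distance.min() + 0.5)
print(f"argmin T = {result.argmin_time} generations (planted: 2,000); "
      f"grid times within tolerance of the minimum: {within.tolist()}")
print("note: at this theta the carrier sample carries very few segregating "
      "sites, so the profile is shallow and the point estimate is broad")

freq_test = establishment_frequency_test(demography, result.argmin_time,
                                         0.254, reps=50_000, seed=3)
(BASE / "insertion_age.json").write_text(json.dumps({
    "grid": result.grid.tolist(),
    "mean_distance": result.mean_distance.tolist(),
    "argmin_T": int(result.argmin_time),
    "drift_test_p": freq_test.p_value,
    "n_established": freq_test.n_established,
}, indent=2) + "\n")
print(f"drift test: P(carrier freq >= 0.254 | established, T="
      f"{result.argmin_time}) = {freq_test.p_value:.3f} "
      f"({freq_test.n_established} established / {freq_test.n_total} replicates)")
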