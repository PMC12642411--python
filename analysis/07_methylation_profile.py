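#!/usr/bin/env python
"""Windowed CpG methylation over the element and the LTR hypomethylation dip.

Discretizes per-CpG scores at 0.5, summarises them in 10-CpG windows (counts
and means), and tests the dip in the LTRs against the element body with a
circular-shift permutation test.
"""

from pathlib import Path

from ervpop import io
from ervpop.methylation import dip_score, window_methylation

BASE = Path(__file__).resolve().parent.parent / "results"
DATA = BASE / "data"

track = io.read_methylation_tsv(DATA / "methylation.tsv")
truth = io.read_bed(DATA / "element_truth.bed").set_index("name")

counts = window_methylation(track, mode="count", cpg_window=10)
means = window_methylation(track, mode="mean", cpg_window=10)
counts.assign(mean_value=means["value"]).to_csv(
    BASE / "methylation_windows.tsv", sep="\t", index=False
)
print(f"{len(track)} CpGs in {len(counts)} windows of 10; "
      f"overall discretized methylation "
      f"{means['value'].mul(means['n_cpg']).sum() / means['n_cpg'].sum():.2f}")

ltr5 = (int(truth.loc["erv_ltr5", "start"]), int(truth.loc["erv_ltr5", "end"]))
ltr3 = (int(truth.loc["erv_ltr3", "start"]), int(truth.loc["erv_ltr3", "end"]))
body = (ltr5[1], ltr3[0])
for name, region in (("5' LTR", ltr5), ("3' LTR", ltr3)):
    result = dip_score(track, region, body, n_perm=1000, seed=4)
    print(f"{name}: dip score {result.score:.2f} vs element body "
          f"(permutation p = {result.p_value:.3f}, "
          f"{result.n_target} CpGs in region)")
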