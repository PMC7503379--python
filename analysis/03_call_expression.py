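#!/usr/bin/env python
"""Call differentially expressed genes in all 36 comparisons.

Single libraries per condition: the negative-binomial exact test runs
at a fixed biological coefficient of variation of 0.2 on TMM-scaled
pseudo-counts; genes with p < 0.05 are DEGs.
"""

import json
import os

import pandas as pd

from methylinta import expression_diff as ed
from methylinta import methylation_diff as md

os.makedirs("results/expression", exist_ok=True)
with open("results/dataset/config.json") as fh:
    samples = json.load(fh)["sample_names"]

counts = ed.read_count_matrix("results/dataset/counts.tsv")
frames = [
    ed.call_degs(counts, a, b)
    for a, b in md.enumerate_comparisons(samples)
]
degs = pd.concat(frames, ignore_index=True)
degs.to_csv("results/expression/degs.tsv", sep="\t", index=False)

n_de = int(degs["is_de"].sum())
per_comp = degs[degs["is_de"]].groupby(["sample_a", "sample_b"]).size()
print(f"{n_de} DEG calls across {len(frames)} comparisons "
      f"({len(counts)} genes)")
print("busiest comparisons:")
print(per_comp.sort_values(ascending=False).head(5).to_string())
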