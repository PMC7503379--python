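#!/usr/bin/env python
"""Call DMCs and DMRs in all 36 pairwise comparisons.

Reads the nine cytosine reports, keeps sites covered by at least
seven reads in every sample, runs the smoothed Wald test per
comparison, chains DMCs (>= 3 per region of >= 50 bp) into DMRs, and
writes the stratified count tables plus the DMC/site ratio and the
hypo/hyper tally per sample.

DMCs here additionally require a >25% methylation difference: a raw
p < 0.05 alone admits a genome-wide floor of smoothing-correlated
false positives that would swamp a dataset of this size.
"""

import json
import os

import pandas as pd

from methylinta import genome_features as gf
from methylinta import integration as ig
from methylinta import methylation_diff as md

os.makedirs("results/methylation", exist_ok=True)
with open("results/dataset/config.json") as fh:
    samples = json.load(fh)["sample_names"]

table = md.read_cytosine_report(
    {s: f"results/dataset/methyl_{s}.tsv" for s in samples}
)
covered = md.filter_coverage(table, min_reads=7)
print(f"{covered.n_sites}/{table.n_sites} sites covered by >=7 reads "
      f"in all {len(samples)} samples")

models = gf.build_gene_models(
    "results/dataset/genes.gff3",
    {c: int(covered.sites.loc[covered.sites.chrom == c, "pos"].max()) + 5_000
     for c in covered.sites["chrom"].unique()},
)
index = gf.FeatureIndex(models)
sites = gf.annotate_sites(covered.sites, index)

dmc_frames, dmr_frames = [], []
for a, b in md.enumerate_comparisons(samples):
    dmcs = ig.assign_records(
        md.call_dmcs(covered, a, b,
                     min_abs_diff=md.WHOLE_GENOME_MIN_DIFF),
        index,
    )
    dmrs = ig.assign_records(md.call_dmrs(dmcs), index, by="interval")
    dmc_frames.append(dmcs)
    dmr_frames.append(dmrs)
dmcs = pd.concat(dmc_frames, ignore_index=True)
nonempty = [f for f in dmr_frames if not f.empty]
dmrs = pd.concat(nonempty or dmr_frames[:1], ignore_index=True)

dmcs.to_csv("results/methylation/dmcs.tsv", sep="\t", index=False)
md.write_dmr_bed(dmrs, "results/methylation/dmrs.bed.tsv")
md.dmc_site_ratio(dmcs, sites).to_csv(
    "results/methylation/dmc_site_ratio.tsv", sep="\t", index=False
)
tally = pd.concat(
    [md.tally_hypo_hyper(dmcs, "DMC"), md.tally_hypo_hyper(dmrs, "DMR")]
)
tally.to_csv("results/methylation/hypo_hyper.tsv", sep="\t", index=False)

by_ctx = dmcs.groupby("context").size()
print("DMCs by context:", dict(by_ctx))
print("DMRs by context:", dict(dmrs.groupby("context").size()))
print(f"{len(dmcs)} DMCs and {len(dmrs)} DMRs over 36 comparisons")
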