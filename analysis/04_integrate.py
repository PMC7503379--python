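#!/usr/bin/env python
"""Join methylation and expression: DEM classes, correlations,
profile clustering, quadrants, and the DMC/DMR-count PCA.

A DEM is a DEG carrying at least one DMC or DMR; a DM gene is
differentially methylated but not expressed.  Gene-level methylation
difference averages the gene's DMR mean differences; DEM profiles
(genes x comparisons) are Ward-clustered and cut dynamically with a
minimum cluster size.
"""

import json
import os

import pandas as pd

from methylinta import genome_features as gf
from methylinta import integration as ig

os.makedirs("results/integration", exist_ok=True)
with open("results/dataset/config.json") as fh:
    samples = json.load(fh)["sample_names"]

dmcs = pd.read_csv("results/methylation/dmcs.tsv", sep="\t")
dmrs_bed = pd.read_csv("results/methylation/dmrs.bed.tsv", sep="\t")
dmrs = pd.DataFrame(
    {
        "chrom": dmrs_bed["chrom"],
        "start": dmrs_bed["start0"] + 1,
        "end": dmrs_bed["end"],
        "context": dmrs_bed["context"],
        "sample_a": dmrs_bed["comparison"].str.split("_vs_").str[0],
        "sample_b": dmrs_bed["comparison"].str.split("_vs_").str[1],
        "n_dmc": dmrs_bed["n_dmc"],
        "mean_diff": dmrs_bed["mean_diff"],
        "direction": dmrs_bed["direction"],
    }
)
degs = pd.read_csv("results/expression/degs.tsv", sep="\t")

sites = pd.read_csv("results/dataset/methyl_Root.tsv", sep="\t")
models = gf.build_gene_models(
    "results/dataset/genes.gff3",
    {c: int(sites.loc[sites.chrom == c, "pos"].max()) + 5_000
     for c in sites["chrom"].unique()},
)
index = gf.FeatureIndex(models)

dem = ig.classify_dem(degs, dmcs, dmrs, index)
dem.to_csv("results/integration/dem.tsv", sep="\t", index=False)
print("classes:", dem["class"].value_counts().to_dict())

dmcs_l = ig.assign_records(dmcs, index)
dmrs_l = ig.assign_records(dmrs, index, by="interval")
for level, recs in (("DMC", dmcs_l), ("DMR", dmrs_l)):
    corr = ig.correlate_expression_methylation(dem, recs, level=level)
    corr.to_csv(f"results/integration/corr_{level.lower()}.tsv",
                sep="\t", index=False)
    cg = corr[(corr.context == "CG") & corr.feature.isin(["exon", "intron"])]
    print(f"{level}-level CG gene-body correlations:")
    print(cg[["feature", "n", "r", "p_value"]].to_string(index=False))

mat = ig.profile_matrix(dem)
clusters = ig.cluster_dem_profiles(mat, min_cluster=5)
clusters.rename("cluster").rename_axis("gene_id").reset_index().to_csv(
    "results/integration/clusters.tsv", sep="\t", index=False
)
print("DEM profile clusters:", clusters.value_counts().to_dict())

quads = pd.concat(
    [ig.quadrant_profile(dem, s) for s in samples], ignore_index=True
)
quads.to_csv("results/integration/quadrants.tsv", sep="\t", index=False)

counts_by_comp = (
    dmcs_l.assign(comparison=dmcs_l.sample_a + "_vs_" + dmcs_l.sample_b)
    .pivot_table(index="comparison", columns=["context", "feature"],
                 values="pos", aggfunc="count", fill_value=0)
)
counts_by_comp.columns = [f"{c}_{f}" for c, f in counts_by_comp.columns]
scores, loadings, frac = ig.count_matrix_pca(counts_by_comp)
scores.to_csv("results/integration/pca_scores.tsv", sep="\t")
loadings.to_csv("results/integration/pca_loadings.tsv", sep="\t")
print("PCA variance fractions:",
      [round(x, 3) for x in frac.head(3).tolist()])
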