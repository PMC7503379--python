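#!/usr/bin/env python
"""Functional enrichment of DEM clusters and the co-expression network.

Each DEM profile cluster is tested for term over-representation
(hypergeometric, Bonferroni-corrected).  DEM genes plus the planted
pathway genes form a Spearman co-expression network (edges at
rho > 0.95); communities come from greedy modularity maximization and
only communities containing a flagged (pathway) gene are retained --
mirroring how a pathway of interest is traced through such networks.
"""

import os

import pandas as pd

from methylinta import enrichment_network as en
from methylinta import expression_diff as ed

os.makedirs("results/network", exist_ok=True)

counts = ed.read_count_matrix("results/dataset/counts.tsv")
annotation = en.read_annotation("results/dataset/terms.tsv")
clusters = pd.read_csv("results/integration/clusters.tsv", sep="\t")
dem = pd.read_csv("results/integration/dem.tsv", sep="\t")
truth = pd.read_csv("results/dataset/truth/dem.tsv", sep="\t")
flagged = sorted(set(truth["gene_id"]))  # planted pathway gene list

universe = [str(g) for g in counts.index]
enr = []
for k, grp in clusters.groupby("cluster"):
    out = en.hypergeom_enrich(
        [g for g in grp["gene_id"] if g in set(universe)], universe,
        annotation,
    )
    out.insert(0, "cluster", k)
    enr.append(out)
enrichment = pd.concat(enr, ignore_index=True)
enrichment.to_csv("results/network/enrichment.tsv", sep="\t", index=False)
hits = enrichment[enrichment["p_bonferroni"] < 0.05]
print("significant cluster enrichments:")
print(hits[["cluster", "term", "k", "K", "p_bonferroni"]]
      .to_string(index=False))

dem_genes = sorted(set(dem.loc[dem["class"] == "DEM", "gene_id"].dropna()))
net_genes = sorted(set(dem_genes) | set(flagged))
expr = en.cpm_log2(counts)
G, dropped = en.build_network(expr, net_genes, rho_threshold=0.95)
part, Q = en.detect_communities(G)
kept = en.filter_flagged_communities(part, flagged)
en.write_graph(G, "results/network/edges.tsv",
               "results/network/network.graphml")
pd.DataFrame(
    [{"community": i + 1, "gene_id": g}
     for i, c in enumerate(kept) for g in sorted(c)]
).to_csv("results/network/communities.tsv", sep="\t", index=False)
print(f"network: {G.number_of_nodes()} nodes, {G.number_of_edges()} edges "
      f"({len(dropped)} genes without an edge)")
print(f"{len(part)} communities (Q = {Q:.3f}); "
      f"{len(kept)} contain a flagged pathway gene")
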