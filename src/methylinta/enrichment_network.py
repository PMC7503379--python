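"""Functional-term enrichment and Spearman co-expression networks.

Enrichment is a one-sided (over-representation) hypergeometric test
per term with Bonferroni correction over the terms tested; terms are
flat labels (GO ids, UniProt keywords, orthology classes -- the source
does not matter here).

The co-expression network connects genes whose expression profiles
across samples have Spearman's rho strictly above a threshold (0.95
by default).  Communities are found by Clauset-Newman-Moore greedy
modularity agglomeration on the unweighted thresholded graph, with a
deterministic tie-break (smallest lexicographic node-id pair) so the
partition is reproducible run to run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats

DEFAULT_RHO = 0.95


def read_annotation(path: str) -> dict[str, set[str]]:
    """TSV with columns gene_id, term (extra columns ignored) ->
    gene -> set of terms."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, set[str]] = {}
    for g, t in zip(df["gene_id"], df["term"]):
        out.setdefault(str(g), set()).add(str(t))
    return out


def hypergeom_enrich(
    query_genes,
    universe_genes,
    annotation: dict[str, set[str]],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of terms in a gene set.

    For each term with K > 0 genes in the universe: p_raw =
    P(X >= k) for k term genes among the n query genes drawn from N
    universe genes; p_bonferroni = min(1, p_raw x #terms tested).
    """
    query = set(query_genes)
    universe = set(universe_genes)
    if not query <= universe:
        extra = sorted(query - universe)[:5]
        raise ValueError(f"query genes outside universe, e.g. {extra}")
    term_genes: dict[str, set[str]] = {}
    for g in universe:
        for t in annotation.get(g, ()):
            term_genes.setdefault(t, set()).add(g)
    N, n = len(universe), len(query)
    rows = []
    for term in sorted(term_genes):
        members = term_genes[term]
        K = len(members)
        k = len(members & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N,
                     "p_raw": min(1.0, p)})
    out = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p_raw"])
    m = len(out)
    out["p_bonferroni"] = np.minimum(1.0, out["p_raw"] * m)
    return out.sort_values("p_raw", kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# co-expression network


def cpm_log2(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(counts-per-million + 1) normalization for network input."""
    lib = counts.sum(axis=0)
    return np.log2(counts.div(lib, axis=1) * 1e6 + 1.0)


def build_network(
    expression: pd.DataFrame,
    gene_set=None,
    rho_threshold: float = DEFAULT_RHO,
) -> tuple[nx.Graph, list[str]]:
    """Spearman co-expression graph over ``gene_set`` (default: all genes).

    ``expression`` is genes x samples (any monotone-equivalent scale;
    Spearman only sees ranks, average ranks on ties).  An edge joins
    two genes iff rho > rho_threshold strictly.  Returns the graph
    (isolated genes dropped) and the sidecar list of dropped genes.
    """
    if expression.shape[1] < 4:
        raise ValueError("need >= 4 samples for a meaningful rank correlation")
    genes = list(expression.index if gene_set is None else gene_set)
    sub = expression.loc[genes]
    X = sub.to_numpy(dtype=float)
    var_ok = X.std(axis=1) > 0
    genes = [g for g, ok in zip(genes, var_ok) if ok]
    X = X[var_ok]
    if len(genes) < 2:
        return nx.Graph(), genes
    rho = stats.spearmanr(X, axis=1).statistic
    rho = np.atleast_2d(rho)
    G = nx.Graph()
    ii, jj = np.where(np.triu(rho > rho_threshold, k=1))
    for i, j in zip(ii, jj):
        G.add_edge(genes[i], genes[j], weight=float(rho[i, j]))
    dropped = sorted(set(genes) - set(G.nodes))
    return G, dropped


def modularity(G: nx.Graph, communities) -> float:
    """Unweighted Newman modularity Q of a partition."""
    return nx.algorithms.community.modularity(G, communities, weight=None)


def detect_communities(G: nx.Graph) -> tuple[list[set[str]], float]:
    """Clauset-Newman-Moore greedy modularity maximization.

    Agglomerates from singletons, always merging the connected
    community pair with the largest modularity gain (ties broken by
    the smallest lexicographic (min id, max id) of the merged pair),
    and returns the partition with the highest Q seen.  Deterministic.
    """
    if G.number_of_nodes() == 0:
        return [], 0.0
    if G.number_of_edges() == 0:
        return [{u} for u in sorted(G.nodes)], 0.0
    m = G.number_of_edges()
    comms: dict[int, set] = {i: {u} for i, u in enumerate(sorted(G.nodes))}
    node_comm = {u: i for i, c in comms.items() for u in c}
    deg = dict(G.degree())
    a = {i: sum(deg[u] for u in c) / (2.0 * m) for i, c in comms.items()}
    # e[i][j] = fraction of edges between communities i and j
    e: dict[int, dict[int, float]] = {i: {} for i in comms}
    for u, v in G.edges():
        i, j = node_comm[u], node_comm[v]
        if i == j:
            continue
        e[i][j] = e[i].get(j, 0.0) + 1.0 / m
        e[j][i] = e[j].get(i, 0.0) + 1.0 / m
    Q = sum(-a[i] ** 2 for i in comms)  # all-singleton partition
    best_Q, best_part = Q, [set(c) for c in comms.values()]

    def pair_key(i, j):
        ui, uj = min(comms[i]), min(comms[j])
        return (min(ui, uj), max(ui, uj))

    while len(comms) > 1:
        best = None
        for i in comms:
            for j, eij in e[i].items():
                if j <= i:
                    continue
                dq = eij - 2.0 * a[i] * a[j]
                key = pair_key(i, j)
                if best is None or dq > best[0] + 1e-12 or (
                    abs(dq - best[0]) <= 1e-12 and key < best[3]
                ):
                    best = (dq, i, j, key)
        if best is None:  # only disconnected communities remain
            break
        dq, i, j, _ = best
        comms[i] |= comms.pop(j)
        a[i] += a.pop(j)
        for k, v in e.pop(j).items():
            if k == i:
                continue
            d = e[k]
            d.pop(j, None)
            e[i][k] = e[i].get(k, 0.0) + v
            d[i] = d.get(i, 0.0) + v
        e[i].pop(j, None)
        Q += dq
        if Q > best_Q + 1e-12:
            best_Q = Q
            best_part = [set(c) for c in comms.values()]
    part = sorted(best_part, key=lambda c: (-len(c), min(c)))
    return part, float(best_Q)


def filter_flagged_communities(
    partition: list[set[str]], flagged_genes
) -> list[set[str]]:
    """Keep communities containing >= 1 flagged gene (e.g. pathway
    genes of interest), renumbered by descending size."""
    flagged = set(flagged_genes)
    kept = [c for c in partition if c & flagged]
    return sorted(kept, key=lambda c: (-len(c), min(c)))


def write_graph(G: nx.Graph, edge_path: str, graphml_path: str | None = None):
    rows = [
        {"gene_a": u, "gene_b": v, "rho": d.get("weight", np.nan)}
        for u, v, d in G.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "rho"]).to_csv(
        edge_path, sep="\t", index=False
    )
    if graphml_path:
        nx.write_graphml(G, graphml_path)
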