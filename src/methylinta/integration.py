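"""Joining differential methylation and differential expression.

For every (gene, comparison) pair the pipeline joins the exact-test
expression call with the gene's differential-methylation evidence
(DMCs and DMRs assigned to its features, flanks included) and
classifies it:

* ``DEM``  -- differentially expressed AND carrying >= 1 DMC or DMR;
* ``DEG-only`` -- differentially expressed, no methylation call;
* ``DM-only``  -- not DE but carrying >= 1 DMC or DMR;
* ``neither``  -- present in the inputs with no call of either kind.

Gene-level methylation difference is the unweighted mean of the
mean_diff of the gene's DMRs.  DEM methylation-difference profiles
(genes x comparisons) are clustered with Ward linkage on Euclidean
distances and cut with a dynamic tree cut honoring a minimum cluster
size (30 by default).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage

from .genome_features import FeatureIndex

DEFAULT_MIN_CLUSTER = 30

CLASSES = ("DEM", "DEG-only", "DM-only", "neither")


def _comparison_key(df: pd.DataFrame) -> pd.Series:
    return df["sample_a"] + "_vs_" + df["sample_b"]


def assign_records(
    records: pd.DataFrame, index: FeatureIndex, by: str = "point"
) -> pd.DataFrame:
    """Attach gene_id / feature labels to DMC (point) or DMR (midpoint)
    records."""
    out = records.copy()
    if records.empty:
        out["gene_id"] = pd.Series(dtype=object)
        out["feature"] = pd.Series(dtype=object)
        return out
    if by == "point":
        labels = [
            index.assign(c, int(p))
            for c, p in zip(records["chrom"], records["pos"])
        ]
    else:
        labels = [
            index.assign_interval(c, int(s), int(e))
            for c, s, e in zip(
                records["chrom"], records["start"], records["end"]
            )
        ]
    out["gene_id"] = [g for g, _ in labels]
    out["feature"] = [f for _, f in labels]
    return out


def summarize_dmrs_per_gene(
    dmrs: pd.DataFrame, index: FeatureIndex | None = None
) -> pd.DataFrame:
    """Mean DMR methylation difference per (gene, comparison).

    DMRs are assigned to genes by midpoint unless ``gene_id`` is
    already present.  The mean is unweighted over the gene's DMRs
    (body and flanks); cancellation of opposite-sign DMRs is possible.
    Genes with no DMR are absent from the output.
    """
    if "gene_id" not in dmrs.columns:
        if index is None:
            raise ValueError("need a FeatureIndex to assign DMRs to genes")
        dmrs = assign_records(dmrs, index, by="interval")
    d = dmrs.dropna(subset=["gene_id"])
    if d.empty:
        return pd.DataFrame(
            columns=["gene_id", "sample_a", "sample_b", "gene_mean_dmr_diff"]
        )
    return (
        d.groupby(["gene_id", "sample_a", "sample_b"])["mean_diff"]
        .mean()
        .rename("gene_mean_dmr_diff")
        .reset_index()
    )


def classify_dem(
    degs: pd.DataFrame,
    dmcs: pd.DataFrame,
    dmrs: pd.DataFrame,
    index: FeatureIndex,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Build the joined DEM table over every gene appearing in any input.

    ``dmcs``/``dmrs`` need not be pre-assigned; assignment uses the
    feature index (DMCs by position, DMRs by midpoint).  Output rows
    are keyed by (gene_id, sample_a, sample_b) and carry logFC, p_expr,
    n_dmc, n_dmr, gene_mean_dmr_diff and the class label.
    """
    if "gene_id" not in dmcs.columns:
        dmcs = assign_records(dmcs, index, by="point")
    if "gene_id" not in dmrs.columns:
        dmrs = assign_records(dmrs, index, by="interval")
    key = ["gene_id", "sample_a", "sample_b"]

    def _counts(df, name):
        df = df.dropna(subset=["gene_id"])
        if df.empty:
            return pd.DataFrame(columns=key + [name])
        return df.groupby(key).size().rename(name).reset_index()

    n_dmc = _counts(dmcs, "n_dmc")
    n_dmr = _counts(dmrs, "n_dmr")
    mdiff = summarize_dmrs_per_gene(dmrs)
    expr = degs[["gene_id", "sample_a", "sample_b", "logFC", "p_value", "tested"]]
    expr = expr.rename(columns={"p_value": "p_expr", "tested": "expr_tested"})
    out = expr.merge(n_dmc, on=key, how="outer").merge(
        n_dmr, on=key, how="outer"
    )
    out = out.merge(mdiff, on=key, how="left")
    for col in ("n_dmc", "n_dmr"):
        out[col] = pd.to_numeric(out[col], errors="coerce").fillna(0).astype(int)
    out["expr_tested"] = np.asarray(
        [bool(x) if pd.notna(x) else False for x in out["expr_tested"]]
    )
    is_de = out["expr_tested"] & (out["p_expr"] < alpha)
    is_dm = (out["n_dmc"] > 0) | (out["n_dmr"] > 0)
    out["class"] = np.select(
        [is_de & is_dm, is_de, is_dm],
        ["DEM", "DEG-only", "DM-only"],
        default="neither",
    )
    return out


def stratified_methylation_diff(
    records: pd.DataFrame, value_col: str
) -> pd.DataFrame:
    """Mean methylation difference per (gene, comparison, context,
    feature) from assigned DMC or DMR records."""
    d = records.dropna(subset=["gene_id"])
    if d.empty:
        return pd.DataFrame(
            columns=["gene_id", "sample_a", "sample_b", "context", "feature",
                     "meth_diff"]
        )
    return (
        d.groupby(["gene_id", "sample_a", "sample_b", "context", "feature"])[
            value_col
        ]
        .mean()
        .rename("meth_diff")
        .reset_index()
    )


def correlate_expression_methylation(
    dem: pd.DataFrame,
    records: pd.DataFrame,
    level: str = "DMC",
    classes: tuple[str, ...] = ("DEM",),
) -> pd.DataFrame:
    """Pearson correlation of expression logFC with methylation
    difference, stratified by context x feature.

    ``records`` are assigned DMC records (``diff``) or DMR records
    (``mean_diff``) depending on ``level``.  Each stratum cell pairs a
    gene-comparison's logFC with its mean methylation difference in
    that stratum; cells with < 3 points or zero variance are reported
    with r = NaN and their n.
    """
    value_col = "diff" if level == "DMC" else "mean_diff"
    strat = stratified_methylation_diff(records, value_col)
    keep = dem[dem["class"].isin(classes)]
    pairs = strat.merge(
        keep[["gene_id", "sample_a", "sample_b", "logFC"]],
        on=["gene_id", "sample_a", "sample_b"],
    )
    rows = []
    for (ctx, feat), grp in pairs.groupby(["context", "feature"]):
        x = grp["meth_diff"].to_numpy()
        y = grp["logFC"].to_numpy()
        n = len(grp)
        if n < 3 or np.std(x) == 0 or np.std(y) == 0:
            rows.append(
                {"context": ctx, "feature": feat, "n": n,
                 "r": np.nan, "p_value": np.nan,
                 "note": "fewer than 3 points" if n < 3 else "zero variance"}
            )
            continue
        r, p = stats.pearsonr(x, y)
        rows.append(
            {"context": ctx, "feature": feat, "n": n, "r": float(r),
             "p_value": float(p), "note": ""}
        )
    return pd.DataFrame(
        rows, columns=["context", "feature", "n", "r", "p_value", "note"]
    )


# ---------------------------------------------------------------------------
# clustering of DEM methylation profiles


def profile_matrix(dem: pd.DataFrame, classes=("DEM",)) -> pd.DataFrame:
    """Genes x comparisons matrix of gene_mean_dmr_diff for the given
    classes; missing cells (no DMR in that comparison) imputed as 0."""
    keep = dem[dem["class"].isin(classes)].copy()
    keep["comparison"] = _comparison_key(keep)
    mat = keep.pivot_table(
        index="gene_id",
        columns="comparison",
        values="gene_mean_dmr_diff",
        aggfunc="mean",
    )
    return mat.fillna(0.0)


def _cut_tree_dynamic(Z: np.ndarray, n: int, min_cluster: int) -> np.ndarray:
    """'Tree' variant of the dynamic cut: recursively split at the
    highest merges, accepting a branch iff it holds >= min_cluster
    leaves, otherwise folding it into the nearest accepted sibling
    cluster (by centroid distance, resolved by the caller)."""
    children: dict[int, tuple[int, int]] = {}
    sizes = np.ones(2 * n - 1, dtype=int)
    for i, (a, b, _, _) in enumerate(Z):
        node = n + i
        children[node] = (int(a), int(b))
        sizes[node] = sizes[int(a)] + sizes[int(b)]

    def leaves(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b = children[node]
        return leaves(a) + leaves(b)

    def split(node: int) -> tuple[list[list[int]], list[list[int]]]:
        """Returns (accepted clusters, small leftover branches)."""
        if node < n or sizes[node] < 2 * min_cluster:
            return [leaves(node)], []
        a, b = children[node]
        if sizes[a] >= min_cluster and sizes[b] >= min_cluster:
            ca, ra = split(a)
            cb, rb = split(b)
            return ca + cb, ra + rb
        small, big = (a, b) if sizes[a] < min_cluster else (b, a)
        cb, rb = split(big)
        return cb, rb + [leaves(small)]

    root = 2 * n - 2
    if n < min_cluster:
        return np.zeros(n, dtype=int)
    accepted, leftovers = split(root)
    return accepted, leftovers


def cluster_dem_profiles(
    mat: pd.DataFrame,
    min_cluster: int = DEFAULT_MIN_CLUSTER,
    metric: str = "euclidean",
) -> pd.Series:
    """Ward-linkage hierarchical clustering with a dynamic tree cut.

    Returns a Series (index = gene ids) of labels K1, K2, ... ordered
    by descending cluster size.  Fewer than ``min_cluster`` genes
    collapse to a single cluster.  ``metric`` may be 'euclidean'
    (default) or 'correlation'.
    """
    n = len(mat)
    if n == 0:
        return pd.Series(dtype=object)
    if n == 1 or n < min_cluster:
        return pd.Series(["K1"] * n, index=mat.index)
    X = mat.to_numpy(dtype=float)
    if metric == "correlation":
        from scipy.spatial.distance import pdist

        Z = linkage(pdist(X, metric="correlation"), method="ward")
    else:
        Z = linkage(X, method="ward")
    out = _cut_tree_dynamic(Z, n, min_cluster)
    if isinstance(out, np.ndarray):  # trivial single-cluster case
        labels = out
    else:
        accepted, leftovers = out
        centroids = [X[c].mean(axis=0) for c in accepted]
        for small in leftovers:
            c = X[small].mean(axis=0)
            d = [np.linalg.norm(c - ctr) for ctr in centroids]
            j = int(np.argmin(d))
            accepted[j] = accepted[j] + small
            centroids[j] = X[accepted[j]].mean(axis=0)
        labels = np.zeros(n, dtype=int)
        for k, members in enumerate(accepted):
            labels[members] = k
    # relabel by descending size, ties by smallest member id
    ids = np.asarray(mat.index.astype(str))
    order = sorted(
        np.unique(labels),
        key=lambda k: (-(labels == k).sum(), min(ids[labels == k])),
    )
    remap = {k: f"K{i + 1}" for i, k in enumerate(order)}
    return pd.Series([remap[k] for k in labels], index=mat.index)


# ---------------------------------------------------------------------------
# quadrants and PCA


def quadrant_profile(dem: pd.DataFrame, focal_sample: str) -> pd.DataFrame:
    """M+/-E+/- quadrant counts for one focal sample.

    Comparisons involving the focal sample are re-oriented so it comes
    first (signs of both the methylation difference and logFC flip
    when it was the second sample).  DEM rows with a zero methylation
    difference or zero logFC are excluded and tallied separately.
    """
    d = dem[dem["class"] == "DEM"]
    d = d[(d["sample_a"] == focal_sample) | (d["sample_b"] == focal_sample)]
    flip = np.where(d["sample_a"] == focal_sample, 1.0, -1.0)
    m = pd.to_numeric(d["gene_mean_dmr_diff"], errors="coerce").to_numpy(
        dtype=float
    ) * flip
    e = pd.to_numeric(d["logFC"], errors="coerce").to_numpy(dtype=float) * flip
    m = np.where(np.isfinite(m), m, 0.0)  # no DMR diff -> excluded as zero
    ok = (m != 0) & (e != 0)
    labels = np.where(m > 0, "M+", "M-") + np.where(e > 0, "E+", "E-")
    counts = pd.Series(labels[ok]).value_counts()
    rows = [
        {"focal": focal_sample, "quadrant": q,
         "count": int(counts.get(q, 0))}
        for q in ("M-E-", "M-E+", "M+E-", "M+E+")
    ]
    rows.append(
        {"focal": focal_sample, "quadrant": "excluded",
         "count": int(len(d) - ok.sum())}
    )
    return pd.DataFrame(rows)


def count_matrix_pca(mat: pd.DataFrame):
    """PCA of a comparisons x (context, feature) DMC/DMR count matrix.

    Columns are standardized (zero-variance columns dropped with a
    warning); returns (scores, loadings, variance_fractions).  Each
    component's sign is fixed so its largest-magnitude loading is
    positive.
    """
    import warnings

    X = mat.to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need >= 2 rows and >= 2 columns")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance column(s)",
            stacklevel=2,
        )
    cols = mat.columns[keep]
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
    # sign convention: largest-|loading| entry positive per component
    for k in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    eig = S**2 / (X.shape[0] - 1)
    frac = eig / eig.sum()
    pcs = [f"PC{i + 1}" for i in range(len(S))]
    scores = pd.DataFrame(U * S, index=mat.index, columns=pcs)
    loadings = pd.DataFrame(Vt.T, index=cols, columns=pcs)
    return scores, loadings, pd.Series(frac, index=pcs)
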