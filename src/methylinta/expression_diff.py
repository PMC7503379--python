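"""Differential expression between sample pairs without replicates.

With one RNA-seq library per condition a dispersion cannot be
estimated, so the negative-binomial dispersion is fixed from an
assumed biological coefficient of variation (BCV): phi = bcv^2, with
bcv = 0.2 by default.  Counts are scaled to a common effective library
size (TMM normalization by default) and compared gene by gene with an
exact conditional test: given the total t of the two pseudo-counts,
the p-value sums the probabilities of all splits (a, t - a) no more
likely than the observed one under independent NB(t/2, phi) margins.

Genes with p < 0.05 are called differentially expressed (DEG).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_BCV = 0.2
DEFAULT_ALPHA = 0.05
PRIOR_COUNT = 0.5


def read_count_matrix(path: str) -> pd.DataFrame:
    """Gene x sample count TSV; first column = gene ids, header = samples."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError("negative counts")
    return df


# ---------------------------------------------------------------------------
# library-size normalization


def _tmm_factor(obs, ref, lib_obs, lib_ref, trim_m=0.3, trim_a=0.05):
    """Weighted trimmed mean of M-values factor for one sample vs reference."""
    keep = (obs > 0) & (ref > 0)
    o, r = obs[keep].astype(float), ref[keep].astype(float)
    if o.size == 0:
        return 1.0
    po, pr = o / lib_obs, r / lib_ref
    M = np.log2(po / pr)
    A = 0.5 * np.log2(po * pr)
    # asymptotic (delta-method) variance of M for precision weights
    w = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    if np.allclose(M, 0):
        return 1.0
    n = M.size
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    rank_m = stats.rankdata(M, method="average")
    rank_a = stats.rankdata(A, method="average")
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any():
        return 1.0
    f = np.sum(M[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
    return float(2.0 ** f)


def normalize_libsizes(
    counts: pd.DataFrame, method: str = "tmm"
) -> pd.Series:
    """Effective library sizes (raw column sum x scaling factor).

    ``method``: 'tmm' (trimmed mean of M-values, trim 30% on M / 5% on
    A, reference = sample whose upper quartile is closest to the mean
    upper quartile), 'upper-quartile', or 'none'.  Factors are
    geometric-mean normalized so they multiply to ~1.
    """
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise ValueError(f"all-zero sample(s): {bad}")
    if counts.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    x = counts.to_numpy(dtype=float)
    if method == "none":
        factors = np.ones(x.shape[1])
    elif method == "upper-quartile":
        uq = np.array(
            [np.quantile(col[col > 0], 0.75) for col in x.T]
        ) / lib.to_numpy()
        factors = uq / np.exp(np.mean(np.log(uq)))
    elif method == "tmm":
        uq = np.array(
            [np.quantile(col[col > 0], 0.75) for col in x.T]
        ) / lib.to_numpy()
        ref = int(np.argmin(np.abs(uq - uq.mean())))
        factors = np.array(
            [
                _tmm_factor(x[:, j], x[:, ref], lib.iloc[j], lib.iloc[ref])
                for j in range(x.shape[1])
            ]
        )
        factors = factors / np.exp(np.mean(np.log(factors)))
    else:
        raise ValueError(f"unknown normalization {method!r}")
    return lib * factors


# ---------------------------------------------------------------------------
# the exact test


def _split_logpmf(t: int, phi: float) -> np.ndarray:
    """log pmf of NB(mean t/2, dispersion phi) at 0..t."""
    mu = t / 2.0
    if phi <= 0:
        return stats.poisson.logpmf(np.arange(t + 1), mu)
    r = 1.0 / phi
    return stats.nbinom.logpmf(np.arange(t + 1), r, r / (r + mu))


def exact_test_pvalue(ya: int, yb: int, phi: float = DEFAULT_BCV**2) -> float:
    """Exact conditional NB p-value for a split (ya, yb) of t = ya + yb.

    Sums P(A = a) * P(B = t - a) over all splits whose joint probability
    is <= that of the observed split (with a small relative tolerance
    for floating-point ties), normalized by the total over all t + 1
    splits.  t = 0 returns 1.
    """
    t = ya + yb
    if t == 0:
        return 1.0
    lp = _split_logpmf(t, phi)
    joint = lp + lp[::-1]
    obs = joint[ya]
    m = joint.max()
    w = np.exp(joint - m)
    keep = joint <= obs + 1e-10
    return float(min(1.0, w[keep].sum() / w.sum()))


def _equalize(ya, yb, lib_a, lib_b):
    """Pseudo-counts at the common (geometric-mean) library size."""
    common = np.sqrt(lib_a * lib_b)
    return (
        int(np.rint(ya * common / lib_a)),
        int(np.rint(yb * common / lib_b)),
    )


def exact_test(
    counts: pd.DataFrame,
    gene: str,
    sample_a: str,
    sample_b: str,
    bcv: float = DEFAULT_BCV,
    eff_lib: pd.Series | None = None,
) -> dict:
    """Exact NB test for one gene; returns gene, logFC, p_value."""
    if eff_lib is None:
        eff_lib = normalize_libsizes(counts)
    ya, yb = int(counts.at[gene, sample_a]), int(counts.at[gene, sample_b])
    a, b = _equalize(ya, yb, eff_lib[sample_a], eff_lib[sample_b])
    p = exact_test_pvalue(a, b, bcv * bcv)
    logfc = 0.0 if a + b == 0 else float(
        np.log2((a + PRIOR_COUNT) / (b + PRIOR_COUNT))
    )
    return {"gene_id": gene, "logFC": logfc, "p_value": p}


def call_degs(
    counts: pd.DataFrame,
    sample_a: str,
    sample_b: str,
    bcv: float = DEFAULT_BCV,
    alpha: float = DEFAULT_ALPHA,
    normalization: str = "tmm",
) -> pd.DataFrame:
    """Exact-test DE calls for every gene in one pairwise comparison.

    Returns gene_id, logFC (A over B), p_value, is_de; genes with zero
    counts in both samples are reported with tested = False.
    """
    for s in (sample_a, sample_b):
        if s not in counts.columns:
            raise KeyError(f"unknown sample {s!r}")
    eff = normalize_libsizes(counts, method=normalization)
    ya = counts[sample_a].to_numpy(dtype=np.int64)
    yb = counts[sample_b].to_numpy(dtype=np.int64)
    common = np.sqrt(eff[sample_a] * eff[sample_b])
    a = np.rint(ya * common / eff[sample_a]).astype(np.int64)
    b = np.rint(yb * common / eff[sample_b]).astype(np.int64)
    phi = bcv * bcv
    # cache p-values per (t, a): many genes share small totals
    pvals = np.ones(len(a))
    cache: dict[int, np.ndarray] = {}
    for i, (ai, bi) in enumerate(zip(a, b)):
        t = int(ai + bi)
        if t == 0:
            continue
        per_t = cache.get(t)
        if per_t is None:
            lp = _split_logpmf(t, phi)
            joint = lp + lp[::-1]
            m = joint.max()
            w = np.exp(joint - m)
            order_p = np.empty(t + 1)
            # p-value for every possible observed split, computed once
            srt = np.argsort(joint, kind="mergesort")
            cw = np.cumsum(w[srt])
            total = cw[-1]
            # inclusive of ties: rightmost index with joint <= joint[obs]+tol
            js = joint[srt]
            for rank, k in enumerate(srt):
                hi = np.searchsorted(js, joint[k] + 1e-10, side="right") - 1
                order_p[k] = min(1.0, cw[hi] / total)
            per_t = order_p
            cache[t] = per_t
        pvals[i] = per_t[int(ai)]
    tested = (a + b) > 0
    logfc = np.where(
        tested, np.log2((a + PRIOR_COUNT) / (b + PRIOR_COUNT)), 0.0
    )
    out = pd.DataFrame(
        {
            "gene_id": counts.index,
            "sample_a": sample_a,
            "sample_b": sample_b,
            "logFC": logfc,
            "p_value": pvals,
            "tested": tested,
        }
    )
    out["is_de"] = tested & (out["p_value"] < alpha)
    return out
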