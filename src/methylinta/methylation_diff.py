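"""Differential methylation calling between pairs of WGBS samples.

The design this package targets has a single bisulfite library per
sample, so site-level differential calls cannot borrow strength from
replicates.  Instead, following the smoothing idea popularized for
such designs, neighboring cytosines of the same context act as
pseudo-replicates: methylation levels are estimated from pooled counts
in a local window, a local beta-binomial dispersion is estimated from
the spread of per-site proportions in that window, and a Wald test on
the difference of smoothed levels gives a per-site p-value.

A DMC (differentially methylated cytosine) is a tested site with
p < alpha, optionally also requiring a minimum absolute methylation
difference (0.25 in whole-genome analyses, 0 in gene-model analyses).
A DMR (region) is a maximal chain of >= 3 same-direction DMCs with
inter-site gaps <= 100 bp spanning >= 50 bp.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

SITE_KEY = ["chrom", "pos", "strand"]
SITE_COLS = SITE_KEY + ["context"]

DEFAULT_MIN_READS = 7
DEFAULT_WINDOW_BP = 500
DEFAULT_ALPHA = 0.05
WHOLE_GENOME_MIN_DIFF = 0.25
DISPERSION_FLOOR = 1e-3
DISPERSION_CAP = 0.5


@dataclass
class MethylTable:
    """Per-site, per-sample methylated/total read counts.

    ``sites`` is a DataFrame (chrom, pos, strand, context) sorted by
    (chrom, pos, strand); ``meth`` and ``total`` are integer arrays of
    shape (n_sites, n_samples) aligned with ``sites`` and ``samples``.
    """

    sites: pd.DataFrame
    samples: list[str]
    meth: np.ndarray
    total: np.ndarray

    def __post_init__(self):
        if (self.meth > self.total).any():
            raise ValueError("methylated count exceeds total count")
        self.sites = self.sites.reset_index(drop=True)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def subset(self, mask: np.ndarray) -> "MethylTable":
        return MethylTable(
            self.sites.loc[mask].reset_index(drop=True),
            list(self.samples),
            self.meth[mask],
            self.total[mask],
        )


def read_cytosine_report(paths: dict[str, str]) -> MethylTable:
    """Merge per-sample cytosine-report TSVs into one :class:`MethylTable`.

    Each file holds columns chrom, pos, strand, context,
    count_methylated, count_total.  The output covers the union of
    sites; a site absent from a sample's file gets total = 0 there.
    """
    frames = {}
    for sample, path in paths.items():
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        if (df["count_methylated"] > df["count_total"]).any():
            raise ValueError(f"{path}: count_methylated > count_total")
        if df.duplicated(SITE_KEY).any():
            raise ValueError(f"{path}: duplicate (chrom, pos, strand) rows")
        frames[sample] = df.set_index(SITE_KEY)
    samples = list(paths)
    contexts = pd.concat(
        [f["context"] for f in frames.values()]
    ).groupby(level=SITE_KEY).first()
    idx = contexts.index
    sites = contexts.reset_index()
    sites = sites.sort_values(SITE_KEY, kind="mergesort").reset_index(drop=True)
    idx = pd.MultiIndex.from_frame(sites[SITE_KEY])
    meth = np.zeros((len(sites), len(samples)), dtype=np.int64)
    total = np.zeros_like(meth)
    for j, sample in enumerate(samples):
        f = frames[sample].reindex(idx)
        meth[:, j] = f["count_methylated"].fillna(0).to_numpy(dtype=np.int64)
        total[:, j] = f["count_total"].fillna(0).to_numpy(dtype=np.int64)
    return MethylTable(sites[SITE_COLS], samples, meth, total)


def write_cytosine_report(table: MethylTable, sample: str, path: str) -> None:
    j = table.sample_index(sample)
    out = table.sites.copy()
    out["count_methylated"] = table.meth[:, j]
    out["count_total"] = table.total[:, j]
    out.to_csv(path, sep="\t", index=False)


def filter_coverage(
    table: MethylTable, min_reads: int = DEFAULT_MIN_READS
) -> MethylTable:
    """Keep only sites covered by >= ``min_reads`` reads in every sample."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    mask = (table.total >= min_reads).all(axis=1)
    return table.subset(mask)


# ---------------------------------------------------------------------------
# smoothing and the Wald test


def _group_slices(sites: pd.DataFrame):
    """Yield (slice, positions) for each contiguous (chrom, context) block.

    Sites are sorted by (chrom, pos); context interleaves within a
    chromosome, so blocks are gathered by index rather than contiguity.
    """
    for _, idx in sites.groupby(["chrom", "context"], sort=False).indices.items():
        idx = np.sort(idx)
        yield idx, sites["pos"].to_numpy()[idx]


def _window_stats(pos, m, n, window_bp):
    """Windowed pooled/per-site statistics for one (chrom, context) block.

    Returns dict of arrays aligned with ``pos``: pooled counts Sm, Sn
    over the +/- window_bp/2 neighborhood (valid sites only, n > 0),
    the count k of valid neighbors, the mean inverse coverage, and the
    sample variance of per-site proportions.
    """
    half = window_bp / 2.0
    lo = np.searchsorted(pos, pos - half, side="left")
    hi = np.searchsorted(pos, pos + half, side="right")
    valid = n > 0
    p = np.divide(m, n, out=np.zeros(len(n), dtype=float), where=valid)
    inv = np.divide(1.0, n, out=np.zeros(len(n), dtype=float), where=valid)

    def wsum(x):
        c = np.concatenate([[0.0], np.cumsum(np.where(valid, x, 0.0))])
        return c[hi] - c[lo]

    k = wsum(np.ones_like(p))
    Sm = wsum(m.astype(float))
    Sn = wsum(n.astype(float))
    Sinv = wsum(inv)
    # per-site proportion variance from first differences of neighbors:
    # E[(p_{i+1} - p_i)^2 / 2] = var(p) for iid noise, and slowly varying
    # local means cancel instead of inflating the estimate
    if len(pos) >= 2:
        pair_ok = valid[1:] & valid[:-1]
        d2 = np.where(pair_ok, 0.5 * (p[1:] - p[:-1]) ** 2, 0.0)
        cpair = np.concatenate([[0.0], np.cumsum(d2)])
        ckn = np.concatenate([[0.0], np.cumsum(pair_ok.astype(float))])
        plo = lo
        phi_idx = np.maximum(hi - 1, lo)
        Sd = cpair[phi_idx] - cpair[plo]
        kd = ckn[phi_idx] - ckn[plo]
    else:
        Sd = np.zeros(len(pos))
        kd = np.zeros(len(pos))
    with np.errstate(invalid="ignore", divide="ignore"):
        var_p = np.where(kd >= 1, Sd / np.maximum(kd, 1), np.nan)
        mean_inv = np.where(k > 0, Sinv / np.maximum(k, 1), np.nan)
    return {"k": k, "Sm": Sm, "Sn": Sn, "var_p": var_p, "mean_inv": mean_inv}


def smooth_levels(
    table: MethylTable, sample: str, window_bp: int = DEFAULT_WINDOW_BP
) -> np.ndarray:
    """Smoothed methylation level per site: pooled m/n over same-context
    same-chromosome neighbors within +/- window_bp/2 (site included).

    NaN where the pooled coverage is zero (site then untestable).
    """
    j = table.sample_index(sample)
    out = np.full(table.n_sites, np.nan)
    for idx, pos in _group_slices(table.sites):
        st = _window_stats(pos, table.meth[idx, j], table.total[idx, j], window_bp)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[idx] = np.where(st["Sn"] > 0, st["Sm"] / st["Sn"], np.nan)
    return out


def _wald_arrays(table, ja, jb, window_bp, dispersion_floor, dispersion_cap):
    """Vectorized smoothed Wald test; returns (diff, p, tested)."""
    n_sites = table.n_sites
    diff = np.full(n_sites, np.nan)
    pval = np.full(n_sites, np.nan)
    tested = np.zeros(n_sites, dtype=bool)
    for idx, pos in _group_slices(table.sites):
        res = []
        for j in (ja, jb):
            m, n = table.meth[idx, j], table.total[idx, j]
            st = _window_stats(pos, m, n, window_bp)
            Sn = st["Sn"]
            with np.errstate(invalid="ignore", divide="ignore"):
                phat = np.where(Sn > 0, st["Sm"] / np.maximum(Sn, 1), np.nan)
                ntilde = np.where(st["k"] > 0, Sn / np.maximum(st["k"], 1), np.nan)
                pq = phat * (1.0 - phat)
                # method-of-moments dispersion: E[var(p_i)] =
                # p(1-p) * (phi + (1-phi) * mean(1/n_i))
                phi = (st["var_p"] / pq - st["mean_inv"]) / (1.0 - st["mean_inv"])
            phi = np.where(np.isfinite(phi), phi, dispersion_floor)
            phi = np.clip(phi, dispersion_floor, dispersion_cap)
            with np.errstate(invalid="ignore", divide="ignore"):
                var = pq * (1.0 + (ntilde - 1.0) * phi) / np.maximum(Sn, 1)
            var = np.where(Sn > 0, var, np.nan)
            ok = (n > 0) & (Sn > 0)
            res.append((phat, var, ok))
        (pa, va, oka), (pb, vb, okb) = res
        ok = oka & okb
        d = pa - pb
        vsum = va + vb
        with np.errstate(invalid="ignore", divide="ignore"):
            z = d / np.sqrt(vsum)
        p = 2.0 * stats.norm.sf(np.abs(z))
        # degenerate windows: zero variance
        zero_v = ok & (vsum == 0)
        p = np.where(zero_v & (d == 0), 1.0, p)
        p = np.where(zero_v & (d != 0), np.finfo(float).tiny, p)
        p = np.maximum(p, np.finfo(float).tiny)
        diff[idx] = np.where(ok, d, np.nan)
        pval[idx] = np.where(ok, p, np.nan)
        tested[idx] = ok
    return diff, pval, tested


def test_comparison(
    table: MethylTable,
    sample_a: str,
    sample_b: str,
    window_bp: int = DEFAULT_WINDOW_BP,
    dispersion_floor: float = DISPERSION_FLOOR,
    dispersion_cap: float = DISPERSION_CAP,
) -> pd.DataFrame:
    """Smoothed Wald test at every site for one two-sample comparison.

    Returns the site table plus ``diff`` (smoothed level A minus B),
    ``p_value`` and ``tested``; untested sites (zero pooled coverage in
    either sample) carry NaN.
    """
    ja, jb = table.sample_index(sample_a), table.sample_index(sample_b)
    diff, pval, tested = _wald_arrays(
        table, ja, jb, window_bp, dispersion_floor, dispersion_cap
    )
    out = table.sites.copy()
    out["sample_a"] = sample_a
    out["sample_b"] = sample_b
    out["diff"] = diff
    out["p_value"] = pval
    out["tested"] = tested
    return out


def wald_test_site(
    table: MethylTable,
    site: tuple[str, int, str],
    sample_a: str,
    sample_b: str,
    window_bp: int = DEFAULT_WINDOW_BP,
    dispersion_floor: float = DISPERSION_FLOOR,
) -> dict:
    """Single-site convenience wrapper around :func:`test_comparison`."""
    res = test_comparison(
        table, sample_a, sample_b, window_bp, dispersion_floor
    )
    row = res[
        (res["chrom"] == site[0])
        & (res["pos"] == site[1])
        & (res["strand"] == site[2])
    ]
    if row.empty:
        raise KeyError(f"site {site} not in table")
    return row.iloc[0].to_dict()


def call_dmcs(
    table: MethylTable,
    sample_a: str,
    sample_b: str,
    alpha: float = DEFAULT_ALPHA,
    min_abs_diff: float = 0.0,
    window_bp: int = DEFAULT_WINDOW_BP,
    dispersion_floor: float = DISPERSION_FLOOR,
    fdr: bool = False,
) -> pd.DataFrame:
    """Call DMCs for one comparison: tested sites with p < alpha and
    |diff| > min_abs_diff.

    ``min_abs_diff`` defaults to 0 (gene-model mode); whole-genome
    analyses use :data:`WHOLE_GENOME_MIN_DIFF` (0.25).  ``fdr`` switches
    the alpha cut to Benjamini-Hochberg-adjusted p-values (off by
    default: raw p < 0.05 is the standard cut here).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    res = test_comparison(
        table, sample_a, sample_b, window_bp, dispersion_floor
    )
    res = res[res["tested"]].drop(columns="tested")
    pcol = res["p_value"].to_numpy()
    if fdr:
        from statsmodels.stats.multitest import multipletests

        pcol = multipletests(pcol, method="fdr_bh")[1]
    keep = (pcol < alpha) & (res["diff"].abs().to_numpy() > min_abs_diff)
    out = res[keep].copy()
    out["direction"] = np.where(out["diff"] > 0, "hyper", "hypo")
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# DMR chaining


def _chain_block(pos, diff, min_dmc, min_span_bp, max_gap_bp):
    """Greedy maximal chains of same-direction DMCs (one chrom+context)."""
    chains = []
    start = 0
    for i in range(1, len(pos) + 1):
        if (
            i == len(pos)
            or pos[i] - pos[i - 1] > max_gap_bp
            or (diff[i] > 0) != (diff[i - 1] > 0)
        ):
            chains.append((start, i))
            start = i
    out = []
    for a, b in chains:
        if b - a >= min_dmc and pos[b - 1] - pos[a] + 1 >= min_span_bp:
            out.append((a, b))
    return out


def call_dmrs(
    dmcs: pd.DataFrame,
    min_dmc: int = 3,
    min_span_bp: int = 50,
    max_gap_bp: int = 100,
) -> pd.DataFrame:
    """Chain DMCs into DMRs.

    Within each (comparison, chromosome, context), consecutive
    same-direction DMCs with gaps <= ``max_gap_bp`` are chained
    greedily; every maximal chain with >= ``min_dmc`` members spanning
    >= ``min_span_bp`` becomes a DMR whose bounds are its outermost
    member positions and whose mean_diff averages the member diffs.
    """
    empty = pd.DataFrame(
        columns=[
            "chrom", "start", "end", "context", "sample_a", "sample_b",
            "n_dmc", "mean_diff", "direction",
        ]
    )
    rows = []
    if dmcs.empty:
        return empty
    group_cols = ["sample_a", "sample_b", "chrom", "context"]
    for key, grp in dmcs.groupby(group_cols, sort=False):
        grp = grp.sort_values("pos", kind="mergesort")
        pos = grp["pos"].to_numpy()
        diff = grp["diff"].to_numpy()
        for a, b in _chain_block(pos, diff, min_dmc, min_span_bp, max_gap_bp):
            rows.append(
                {
                    "chrom": key[2],
                    "start": int(pos[a]),
                    "end": int(pos[b - 1]),
                    "context": key[3],
                    "sample_a": key[0],
                    "sample_b": key[1],
                    "n_dmc": b - a,
                    "mean_diff": float(diff[a:b].mean()),
                    "direction": "hyper" if diff[a] > 0 else "hypo",
                }
            )
    if not rows:
        return empty
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["sample_a", "sample_b", "chrom", "start"], kind="mergesort"
    ).reset_index(drop=True)


def write_dmr_bed(dmrs: pd.DataFrame, path: str) -> None:
    """BED-like TSV: chrom, start0, end, name, mean_diff, direction, ..."""
    out = pd.DataFrame(
        {
            "chrom": dmrs["chrom"],
            "start0": dmrs["start"] - 1,
            "end": dmrs["end"],
            "name": [
                f"DMR_{c}_{s}_{e}" for c, s, e in
                zip(dmrs["chrom"], dmrs["start"], dmrs["end"])
            ],
            "mean_diff": dmrs["mean_diff"],
            "direction": dmrs["direction"],
            "n_dmc": dmrs["n_dmc"],
            "context": dmrs["context"],
            "comparison": dmrs["sample_a"] + "_vs_" + dmrs["sample_b"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# summaries


def tally_hypo_hyper(records: pd.DataFrame, kind: str = "DMC") -> pd.DataFrame:
    """Hyper/hypo counts per focal sample versus each other sample.

    Each record of comparison (A, B) counts with its direction for
    focal sample A and with the opposite direction for focal sample B.
    """
    cols = ["focal", "other", "direction", "kind", "count"]
    if records.empty:
        return pd.DataFrame(columns=cols)
    flip = {"hyper": "hypo", "hypo": "hyper"}
    fwd = records[["sample_a", "sample_b", "direction"]].rename(
        columns={"sample_a": "focal", "sample_b": "other"}
    )
    rev = pd.DataFrame(
        {
            "focal": records["sample_b"],
            "other": records["sample_a"],
            "direction": records["direction"].map(flip),
        }
    )
    both = pd.concat([fwd, rev], ignore_index=True)
    out = (
        both.groupby(["focal", "other", "direction"])
        .size()
        .rename("count")
        .reset_index()
    )
    out["kind"] = kind
    return out[cols]


def dmc_site_ratio(
    dmcs: pd.DataFrame, sites: pd.DataFrame
) -> pd.DataFrame:
    """#DMC / #covered sites per (feature, context) stratum.

    Both inputs must carry ``feature`` and ``context`` columns (see
    :func:`methylinta.genome_features.annotate_sites`).  Strata present
    in ``sites`` but without DMCs get ratio 0; strata with zero covered
    sites are undefined (NaN) rather than zero.
    """
    n_sites = sites.groupby(["feature", "context"]).size().rename("n_sites")
    n_dmc = (
        dmcs.groupby(["feature", "context"]).size().rename("n_dmc")
        if not dmcs.empty
        else pd.Series(dtype=np.int64, name="n_dmc")
    )
    out = pd.concat([n_sites, n_dmc], axis=1).fillna({"n_dmc": 0}).reset_index()
    out["ratio"] = np.where(
        out["n_sites"].fillna(0) > 0, out["n_dmc"] / out["n_sites"], np.nan
    )
    return out


def enumerate_comparisons(samples: list[str]) -> list[tuple[str, str]]:
    """All unordered sample pairs, in input order (9 samples -> 36)."""
    return list(itertools.combinations(samples, 2))
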