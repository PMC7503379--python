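"""Coverage filtering, smoothed Wald testing, and DMC/DMR calling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methylinta import methylation_diff as md
from conftest import make_methyl_table


class TestReader:
    def _write(self, path, rows):
        pd.DataFrame(
            rows,
            columns=["chrom", "pos", "strand", "context",
                     "count_methylated", "count_total"],
        ).to_csv(path, sep="\t", index=False)

    def test_merge_two_files_same_site(self, tmp_path):
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        self._write(a, [("c1", 10, "+", "CG", 3, 9)])
        self._write(b, [("c1", 10, "+", "CG", 5, 8)])
        t = md.read_cytosine_report({"A": str(a), "B": str(b)})
        assert t.n_sites == 1 and t.samples == ["A", "B"]
        assert t.meth.tolist() == [[3, 5]] and t.total.tolist() == [[9, 8]]

    def test_missing_site_gets_zero_coverage(self, tmp_path):
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        self._write(a, [("c1", 10, "+", "CG", 3, 9),
                        ("c1", 20, "+", "CHH", 1, 7)])
        self._write(b, [("c1", 10, "+", "CG", 5, 8)])
        t = md.read_cytosine_report({"A": str(a), "B": str(b)})
        assert t.n_sites == 2
        row = t.sites.index[t.sites["pos"] == 20][0]
        assert t.total[row, 1] == 0

    def test_round_trip(self, tmp_path):
        a = tmp_path / "a.tsv"
        self._write(a, [("c1", 10, "+", "CG", 3, 9),
                        ("c2", 5, "-", "CHG", 0, 12)])
        t = md.read_cytosine_report({"A": str(a)})
        out = tmp_path / "out.tsv"
        md.write_cytosine_report(t, "A", str(out))
        assert pd.read_csv(out, sep="\t").equals(pd.read_csv(a, sep="\t"))

    def test_input_errors(self, tmp_path):
        a = tmp_path / "a.tsv"
        self._write(a, [("c1", 10, "+", "CG", 9, 3)])
        with pytest.raises(ValueError, match="count_methylated"):
            md.read_cytosine_report({"A": str(a)})
        self._write(a, [("c1", 10, "+", "CG", 1, 3),
                        ("c1", 10, "+", "CG", 2, 3)])
        with pytest.raises(ValueError, match="duplicate"):
            md.read_cytosine_report({"A": str(a)})


class TestCoverageFilter:
    def test_boundary(self):
        t = make_methyl_table([10, 20], meth=[[1, 1], [1, 1]],
                              total=[[7, 7], [7, 6]])
        kept = md.filter_coverage(t, 7)
        assert kept.sites["pos"].tolist() == [10]

    def test_matches_row_wise_oracle(self):
        rng = np.random.default_rng(0)
        total = rng.integers(0, 15, size=(200, 4))
        meth = rng.binomial(total, 0.5)
        t = make_methyl_table(np.arange(1, 201) * 3, meth, total)
        kept = md.filter_coverage(t, 7)
        expect = [i for i in range(200) if all(total[i] >= 7)]
        assert kept.sites["pos"].tolist() == [(i + 1) * 3 for i in expect]

    def test_min_reads_validated(self):
        t = make_methyl_table([10], [[1, 1]], [[7, 7]])
        with pytest.raises(ValueError):
            md.filter_coverage(t, 0)


class TestSmoothing:
    def test_isolated_site(self):
        t = make_methyl_table([1000], [[5, 0]], [[10, 0]])
        assert md.smooth_levels(t, "A")[0] == 0.5

    def test_pooled_counts(self):
        t = make_methyl_table([100, 200], [[10, 0], [0, 0]],
                              [[10, 1], [10, 1]])
        p = md.smooth_levels(t, "A", window_bp=500)
        assert np.allclose(p, [0.5, 0.5])

    def test_matches_all_pairs_window_oracle(self):
        rng = np.random.default_rng(1)
        n = 120
        pos = np.sort(rng.choice(np.arange(1, 5000), size=n, replace=False))
        ctx = rng.choice(["CG", "CHG", "CHH"], size=n)
        total = rng.integers(0, 30, size=(n, 2))
        meth = rng.binomial(total, 0.4)
        t = make_methyl_table(pos, meth, total, context=list(ctx))
        got = md.smooth_levels(t, "A", window_bp=500)
        for i in range(n):
            num = den = 0
            for j in range(n):
                if ctx[j] == ctx[i] and abs(int(pos[j]) - int(pos[i])) <= 250:
                    num += meth[j, 0]
                    den += total[j, 0]
            if den == 0:
                assert np.isnan(got[i])
            else:
                assert got[i] == pytest.approx(num / den, abs=1e-12)


def independent_wald(t, i, ja, jb, window_bp=500, floor=1e-3, cap=0.5):
    """Direct re-evaluation of the test statistic outside the pipeline."""
    pos = t.sites["pos"].to_numpy()
    ctx = t.sites["context"].to_numpy()
    chrom = t.sites["chrom"].to_numpy()
    stats_ = []
    for j in (ja, jb):
        m, n = t.meth[:, j], t.total[:, j]
        win = [
            k for k in range(t.n_sites)
            if chrom[k] == chrom[i] and ctx[k] == ctx[i]
            and abs(int(pos[k]) - int(pos[i])) <= window_bp / 2 and n[k] > 0
        ]
        Sm = sum(int(m[k]) for k in win)
        Sn = sum(int(n[k]) for k in win)
        phat = Sm / Sn
        ntilde = Sn / len(win)
        mean_inv = np.mean([1 / n[k] for k in win])
        props = [m[k] / n[k] for k in win]
        pairs = [
            (a, b) for a, b in zip(win, win[1:])
        ]
        if pairs:
            var_p = np.mean(
                [0.5 * (m[b] / n[b] - m[a] / n[a]) ** 2 for a, b in pairs]
            )
            pq = phat * (1 - phat)
            phi = (var_p / pq - mean_inv) / (1 - mean_inv) if pq > 0 else floor
        else:
            phi = floor
        phi = min(max(phi, floor), cap)
        var = phat * (1 - phat) * (1 + (ntilde - 1) * phi) / Sn
        stats_.append((phat, var))
    (pa, va), (pb, vb) = stats_
    diff = pa - pb
    if va + vb == 0:
        return diff, 1.0 if diff == 0 else np.finfo(float).tiny
    z = diff / np.sqrt(va + vb)
    return diff, 2 * stats.norm.sf(abs(z))


class TestWaldTest:
    def test_identical_counts_null(self):
        t = make_methyl_table([100, 160, 220],
                              meth=[[4, 4], [7, 7], [2, 2]],
                              total=[[10, 10], [12, 12], [9, 9]])
        res = md.test_comparison(t, "A", "B")
        assert np.allclose(res["diff"], 0)
        assert np.allclose(res["p_value"], 1)

    def test_antisymmetry(self):
        rng = np.random.default_rng(2)
        pos = np.sort(rng.choice(np.arange(1, 4000), 60, replace=False))
        total = rng.integers(7, 40, size=(60, 2))
        meth = rng.binomial(total, rng.uniform(0.1, 0.9, size=(60, 1)))
        t = make_methyl_table(pos, meth, total)
        ab = md.test_comparison(t, "A", "B")
        ba = md.test_comparison(t, "B", "A")
        assert np.allclose(ab["diff"], -ba["diff"], atol=1e-12)
        assert np.allclose(ab["p_value"], ba["p_value"], atol=1e-12)

    def test_matches_independent_formula_on_toy_table(self):
        # 3 CG sites, two within one window, one isolated
        t = make_methyl_table(
            [1_000, 1_120, 9_000],
            meth=[[9, 2], [8, 3], [1, 7]],
            total=[[12, 11], [10, 13], [9, 8]],
        )
        res = md.test_comparison(t, "A", "B")
        for i in range(3):
            diff, p = independent_wald(t, i, 0, 1)
            assert res["diff"][i] == pytest.approx(diff, abs=1e-12)
            assert res["p_value"][i] == pytest.approx(p, abs=1e-12)

    def test_single_site_wrapper(self):
        t = make_methyl_table([500], [[5, 1]], [[10, 10]])
        row = md.wald_test_site(t, ("chr1", 500, "+"), "A", "B")
        assert row["diff"] == pytest.approx(0.4)


class TestCallDmcs:
    def test_thresholds(self):
        rng = np.random.default_rng(3)
        pos = np.sort(rng.choice(np.arange(1, 20_000), 300, replace=False))
        total = np.full((300, 2), 30)
        p_true = np.where(
            (np.arange(300) % 3 == 0)[:, None], [[0.8, 0.2]], [[0.5, 0.5]]
        )
        meth = rng.binomial(30, p_true)
        t = make_methyl_table(pos, meth, total)
        res = md.test_comparison(t, "A", "B")
        dmcs = md.call_dmcs(t, "A", "B", alpha=0.05, min_abs_diff=0.25)
        expect = res[(res["p_value"] < 0.05) & (res["diff"].abs() > 0.25)]
        assert dmcs["pos"].tolist() == expect["pos"].tolist()
        assert (np.sign(dmcs["diff"]) ==
                np.where(dmcs["direction"] == "hyper", 1, -1)).all()
        # gene-model mode keeps small-difference calls
        lax = md.call_dmcs(t, "A", "B", alpha=0.05, min_abs_diff=0.0)
        assert len(lax) >= len(dmcs)

    def test_alpha_validated(self):
        t = make_methyl_table([10], [[1, 1]], [[9, 9]])
        with pytest.raises(ValueError):
            md.call_dmcs(t, "A", "B", alpha=0.0)


def brute_force_dmrs(pos, diff, min_dmc=3, min_span_bp=50, max_gap_bp=100):
    """Exhaustive enumeration of maximal valid same-direction chains."""
    n = len(pos)

    def ok(i, j):  # contiguous run [i, j] inclusive
        if any(np.sign(diff[k]) != np.sign(diff[i]) for k in range(i, j + 1)):
            return False
        if any(pos[k + 1] - pos[k] > max_gap_bp for k in range(i, j)):
            return False
        return True

    out = []
    for i in range(n):
        for j in range(i, n):
            if not ok(i, j):
                continue
            maximal = not (i > 0 and ok(i - 1, j)) and not (
                j < n - 1 and ok(i, j + 1)
            )
            if not maximal:
                continue
            if j - i + 1 >= min_dmc and pos[j] - pos[i] + 1 >= min_span_bp:
                out.append((int(pos[i]), int(pos[j]), j - i + 1))
    return sorted(out)


def dmc_frame(pos, diff):
    return pd.DataFrame(
        {
            "chrom": "c1", "pos": pos, "strand": "+", "context": "CG",
            "sample_a": "A", "sample_b": "B", "diff": diff,
            "p_value": 0.01,
            "direction": np.where(np.asarray(diff) > 0, "hyper", "hypo"),
        }
    )


class TestCallDmrs:
    def test_three_dmc_example(self):
        dmrs = md.call_dmrs(dmc_frame([100, 120, 160], [0.3, 0.4, 0.3]))
        assert len(dmrs) == 1
        r = dmrs.iloc[0]
        assert (r["start"], r["end"], r["n_dmc"]) == (100, 160, 3)
        assert r["mean_diff"] == pytest.approx((0.3 + 0.4 + 0.3) / 3)
        assert r["direction"] == "hyper"

    def test_too_few_dmcs(self):
        assert md.call_dmrs(dmc_frame([100, 130], [0.3, 0.3])).empty

    def test_span_too_short(self):
        assert md.call_dmrs(dmc_frame([100, 110, 120], [0.3] * 3)).empty

    def test_direction_break_splits_chain(self):
        dmrs = md.call_dmrs(
            dmc_frame([100, 130, 160, 190, 220, 250],
                      [0.3, 0.3, 0.3, -0.3, -0.3, -0.3])
        )
        assert len(dmrs) == 2
        assert dmrs["direction"].tolist() == ["hyper", "hypo"]

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for trial in range(300):
            k = int(rng.integers(1, 21))
            pos = np.sort(rng.choice(np.arange(1, 600), k, replace=False))
            diff = rng.uniform(-0.6, 0.6, k)
            diff[diff == 0] = 0.1
            got = md.call_dmrs(dmc_frame(pos, diff))
            got_t = sorted(
                (int(r.start), int(r.end), int(r.n_dmc))
                for r in got.itertuples()
            )
            assert got_t == brute_force_dmrs(pos, diff), f"trial {trial}"

    def test_monotonicity_in_min_dmc_and_span(self):
        rng = np.random.default_rng(6)
        pos = np.sort(rng.choice(np.arange(1, 2000), 40, replace=False))
        diff = rng.uniform(-0.5, 0.5, 40)
        base = len(md.call_dmrs(dmc_frame(pos, diff)))
        for min_dmc in (3, 4, 5, 8):
            for span in (50, 100, 300):
                n = len(md.call_dmrs(dmc_frame(pos, diff), min_dmc, span))
                assert n <= base

    def test_dmr_members_revalidate(self):
        rng = np.random.default_rng(7)
        pos = np.sort(rng.choice(np.arange(1, 3000), 80, replace=False))
        diff = rng.uniform(-0.5, 0.5, 80)
        dmcs = dmc_frame(pos, diff)
        for r in md.call_dmrs(dmcs).itertuples():
            members = dmcs[(dmcs.pos >= r.start) & (dmcs.pos <= r.end)]
            assert len(members) == r.n_dmc
            assert r.end - r.start + 1 >= 50
            assert (np.sign(members["diff"]) ==
                    (1 if r.direction == "hyper" else -1)).all()
            gaps = np.diff(members["pos"].to_numpy())
            assert (gaps <= 100).all()


class TestTallies:
    def test_direction_flip(self):
        recs = dmc_frame([100], [0.3])
        tally = md.tally_hypo_hyper(recs, kind="DMC")
        a = tally[(tally.focal == "A")].iloc[0]
        b = tally[(tally.focal == "B")].iloc[0]
        assert a["direction"] == "hyper" and a["count"] == 1
        assert b["direction"] == "hypo" and b["count"] == 1

    def test_empty(self):
        assert md.tally_hypo_hyper(dmc_frame([], [])[0:0]).empty

    def test_matches_group_by_oracle(self):
        rng = np.random.default_rng(8)
        recs = pd.concat(
            [
                dmc_frame(
                    np.sort(rng.choice(2000, 30, replace=False)),
                    rng.uniform(-0.5, 0.5, 30),
                ).assign(sample_a=a, sample_b=b)
                for a, b in [("A", "B"), ("A", "C"), ("B", "C")]
            ]
        )
        tally = md.tally_hypo_hyper(recs)
        for _, row in tally.iterrows():
            if row["focal"] < row["other"]:
                sub = recs[(recs.sample_a == row["focal"]) &
                           (recs.sample_b == row["other"])]
                want = (sub["direction"] == row["direction"]).sum()
            else:
                sub = recs[(recs.sample_a == row["other"]) &
                           (recs.sample_b == row["focal"])]
                want = (sub["direction"] != row["direction"]).sum()
            assert row["count"] == want


class TestDmcSiteRatio:
    def test_basic_ratio_and_undefined_stratum(self):
        sites = pd.DataFrame(
            {"feature": ["exon"] * 100 + ["intron"] * 0 + ["upstream"] * 5,
             "context": ["CG"] * 105}
        )
        dmcs = pd.DataFrame({"feature": ["exon", "exon"], "context": ["CG"] * 2})
        out = md.dmc_site_ratio(dmcs, sites)
        exon = out[(out.feature == "exon")].iloc[0]
        assert exon["ratio"] == pytest.approx(0.02)
        up = out[(out.feature == "upstream")].iloc[0]
        assert up["ratio"] == pytest.approx(0.0)

    def test_matches_double_group_by(self):
        rng = np.random.default_rng(9)
        feats = rng.choice(["exon", "intron", "upstream"], 500)
        ctxs = rng.choice(["CG", "CHG", "CHH"], 500)
        sites = pd.DataFrame({"feature": feats, "context": ctxs})
        sel = rng.random(500) < 0.1
        dmcs = sites[sel]
        out = md.dmc_site_ratio(dmcs, sites)
        for _, row in out.iterrows():
            denom = ((feats == row["feature"]) & (ctxs == row["context"])).sum()
            num = ((dmcs.feature == row["feature"]) &
                   (dmcs.context == row["context"])).sum()
            assert row["ratio"] == pytest.approx(num / denom)


def test_comparison_enumeration():
    nine = [f"S{i}" for i in range(9)]
    assert len(md.enumerate_comparisons(nine)) == 36
    assert md.enumerate_comparisons(["A", "B"]) == [("A", "B")]
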