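"""DEM classification, correlation, clustering, quadrants, PCA."""

import numpy as np
import pandas as pd
import pytest

from methylinta import integration as ig
from methylinta import genome_features as gf


@pytest.fixture(scope="module")
def toy_models():
    models = [
        gf.assemble_gene_model("gA", "c1", "+", 20_000, 22_000,
                               [(20_000, 22_000)], [], [], 100_000),
        gf.assemble_gene_model("gB", "c1", "+", 50_000, 52_000,
                               [(50_000, 52_000)], [], [], 100_000),
    ]
    return models, gf.FeatureIndex(models)


def dmr_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "context", "sample_a", "sample_b",
                 "n_dmc", "mean_diff", "direction"],
    )


def deg_frame(rows):
    df = pd.DataFrame(
        rows, columns=["gene_id", "sample_a", "sample_b", "logFC", "p_value"]
    )
    df["tested"] = True
    df["is_de"] = df["p_value"] < 0.05
    return df


class TestSummarizeDmrs:
    def test_single_and_cancelling_dmrs(self, toy_models):
        _, index = toy_models
        one = dmr_frame(
            [("c1", 20_100, 20_200, "CG", "A", "B", 3, 0.3, "hyper")]
        )
        got = ig.summarize_dmrs_per_gene(one, index)
        assert got.iloc[0]["gene_mean_dmr_diff"] == pytest.approx(0.3)
        two = dmr_frame(
            [("c1", 20_100, 20_200, "CG", "A", "B", 3, 0.2, "hyper"),
             ("c1", 21_000, 21_100, "CG", "A", "B", 3, -0.2, "hypo")]
        )
        got = ig.summarize_dmrs_per_gene(two, index)
        assert got.iloc[0]["gene_mean_dmr_diff"] == pytest.approx(0.0)

    def test_matches_group_by_oracle(self, toy_models):
        _, index = toy_models
        rng = np.random.default_rng(0)
        rows = []
        for _ in range(60):
            s = int(rng.choice([20_100, 21_000, 50_500, 80_000]))
            rows.append(("c1", s, s + 80, "CG",
                         *rng.choice([("A", "B"), ("A", "C")]),
                         3, float(rng.uniform(-0.5, 0.5)), "hyper"))
        dmrs = dmr_frame(rows)
        got = ig.summarize_dmrs_per_gene(dmrs, index)
        labeled = ig.assign_records(dmrs, index, by="interval")
        labeled = labeled.dropna(subset=["gene_id"])
        want = labeled.groupby(["gene_id", "sample_a", "sample_b"])[
            "mean_diff"
        ].mean()
        for r in got.itertuples():
            assert r.gene_mean_dmr_diff == pytest.approx(
                want[(r.gene_id, r.sample_a, r.sample_b)]
            )


class TestClassifyDem:
    def test_class_definitions(self, toy_models):
        _, index = toy_models
        degs = deg_frame(
            [("gA", "A", "B", -2.0, 0.001),   # DE with a DMC -> DEM
             ("gB", "A", "B", 1.0, 0.5),      # not DE, has DMRs -> DM-only
             ("gC", "A", "B", 2.0, 0.01),     # DE, no methylation -> DEG-only
             ("gD", "A", "B", 0.1, 0.9)]      # nothing -> neither
        )
        dmcs = pd.DataFrame(
            {"chrom": ["c1"], "pos": [20_050], "strand": "+",
             "context": "CHH", "sample_a": "A", "sample_b": "B",
             "diff": [0.3], "p_value": [0.01], "direction": ["hyper"]}
        )
        dmrs = dmr_frame(
            [("c1", 50_100, 50_300, "CG", "A", "B", 4, 0.2, "hyper"),
             ("c1", 51_000, 51_200, "CG", "A", "B", 3, 0.1, "hyper")]
        )
        dem = ig.classify_dem(degs, dmcs, dmrs, index)
        cls = dem.set_index("gene_id")["class"]
        assert cls["gA"] == "DEM"
        assert cls["gB"] == "DM-only"
        assert cls["gC"] == "DEG-only"
        assert cls["gD"] == "neither"

    def test_partition_covers_all_inputs(self, toy_models):
        _, index = toy_models
        degs = deg_frame([("gA", "A", "B", 0.5, 0.2)])
        dmrs = dmr_frame(
            [("c1", 50_100, 50_300, "CG", "A", "B", 4, 0.2, "hyper")]
        )
        dem = ig.classify_dem(degs, pd.DataFrame(), dmrs, index)
        assert set(dem["gene_id"]) == {"gA", "gB"}
        assert dem["class"].isin(ig.CLASSES).all()


class TestCorrelation:
    def _dem(self, genes, logfcs):
        return pd.DataFrame(
            {"gene_id": genes, "sample_a": "A", "sample_b": "B",
             "logFC": logfcs, "class": "DEM"}
        )

    def _records(self, genes, diffs):
        return pd.DataFrame(
            {"gene_id": genes, "sample_a": "A", "sample_b": "B",
             "context": "CG", "feature": "exon", "diff": diffs}
        )

    def test_perfect_anticorrelation(self):
        genes = [f"g{i}" for i in range(5)]
        diffs = np.linspace(0.1, 0.5, 5)
        out = ig.correlate_expression_methylation(
            self._dem(genes, -2 * diffs), self._records(genes, diffs)
        )
        assert out.iloc[0]["r"] == pytest.approx(-1.0)

    def test_two_points_undefined(self):
        out = ig.correlate_expression_methylation(
            self._dem(["g0", "g1"], [1.0, 2.0]),
            self._records(["g0", "g1"], [0.1, 0.2]),
        )
        row = out.iloc[0]
        assert np.isnan(row["r"]) and row["n"] == 2

    def test_matches_closed_form(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(40)]
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        out = ig.correlate_expression_methylation(
            self._dem(genes, y), self._records(genes, x)
        )
        r_formula = (
            ((x - x.mean()) * (y - y.mean())).sum()
            / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        assert out.iloc[0]["r"] == pytest.approx(r_formula, abs=1e-12)


class TestClustering:
    @pytest.fixture()
    def blobs(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 1, (40, 6)), rng.normal(10, 1, (40, 6))])
        return pd.DataFrame(X, index=[f"g{i:02d}" for i in range(80)])

    def test_two_blobs_exact_recovery(self, blobs):
        labels = ig.cluster_dem_profiles(blobs, min_cluster=30)
        assert labels.nunique() == 2
        first, second = labels.iloc[:40], labels.iloc[40:]
        assert first.nunique() == 1 and second.nunique() == 1
        assert first.iloc[0] != second.iloc[0]

    def test_min_size_forces_single_cluster(self, blobs):
        labels = ig.cluster_dem_profiles(blobs.iloc[:29], min_cluster=30)
        assert labels.nunique() == 1

    def test_order_invariance(self, blobs):
        a = ig.cluster_dem_profiles(blobs, 30)
        b = ig.cluster_dem_profiles(
            blobs.sample(frac=1, random_state=3), 30
        ).reindex(a.index)
        assert (a == b).all()

    def test_correlation_metric_supported(self, blobs):
        labels = ig.cluster_dem_profiles(blobs, 30, metric="correlation")
        assert set(labels) <= {f"K{i}" for i in range(1, 81)}


class TestQuadrants:
    def _dem(self, rows):
        return pd.DataFrame(
            rows,
            columns=["gene_id", "sample_a", "sample_b",
                     "gene_mean_dmr_diff", "logFC", "class"],
        )

    def test_hypomethylated_overexpressed(self):
        dem = self._dem([("g", "A", "B", -0.2, 1.5, "DEM")])
        out = ig.quadrant_profile(dem, "A").set_index("quadrant")["count"]
        assert out["M-E+"] == 1 and out[["M-E-", "M+E-", "M+E+"]].sum() == 0

    def test_orientation_flip_permutes_quadrants(self):
        dem = self._dem([("g", "A", "B", -0.2, 1.5, "DEM")])
        a = ig.quadrant_profile(dem, "A").set_index("quadrant")["count"]
        b = ig.quadrant_profile(dem, "B").set_index("quadrant")["count"]
        assert a["M-E+"] == b["M+E-"] == 1

    def test_matches_sign_group_by_and_exclusions(self):
        rng = np.random.default_rng(4)
        rows = []
        for i in range(100):
            rows.append((f"g{i}", "A", "B",
                         float(rng.choice([-0.3, 0.0, 0.4])),
                         float(rng.choice([-2.0, 1.0])), "DEM"))
        dem = self._dem(rows)
        out = ig.quadrant_profile(dem, "A").set_index("quadrant")["count"]
        m = dem["gene_mean_dmr_diff"]
        e = dem["logFC"]
        assert out["excluded"] == (m == 0).sum()
        assert out["M-E+"] == ((m < 0) & (e > 0)).sum()
        assert out["M+E-"] == ((m > 0) & (e < 0)).sum()
        assert out.sum() == len(dem)


class TestPca:
    def test_rank_one_matrix(self):
        rng = np.random.default_rng(5)
        M = pd.DataFrame(np.outer(rng.normal(size=8), rng.normal(size=5)))
        _, _, frac = ig.count_matrix_pca(M)
        assert frac.iloc[0] == pytest.approx(1.0, abs=1e-10)

    def test_row_rotation_preserves_eigenvalues(self):
        rng = np.random.default_rng(6)
        M = pd.DataFrame(rng.normal(size=(10, 6)))
        _, _, f1 = ig.count_matrix_pca(M)
        _, _, f2 = ig.count_matrix_pca(M.iloc[::-1])
        assert np.allclose(f1, f2, atol=1e-12)

    def test_matches_eigendecomposition(self):
        rng = np.random.default_rng(7)
        M = pd.DataFrame(rng.normal(size=(10, 6)))
        scores, loadings, frac = ig.count_matrix_pca(M)
        Xs = (M - M.mean()) / M.std(ddof=1)
        eig = np.sort(np.linalg.eigvalsh(np.cov(Xs.T)))[::-1]
        assert np.allclose(frac * eig.sum(), eig, atol=1e-10)
        # scores reproduce the standardized data through the loadings
        assert np.allclose(scores.to_numpy() @ loadings.to_numpy().T,
                           Xs.to_numpy(), atol=1e-10)

    def test_zero_variance_column_dropped(self):
        rng = np.random.default_rng(8)
        M = pd.DataFrame(rng.normal(size=(6, 3)), columns=["a", "b", "c"])
        M["c"] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            _, loadings, _ = ig.count_matrix_pca(M)
        assert "c" not in loadings.index
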