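"""Aggregation, dissimilarities, NMDS, PERMANOVA, betadisper, envfit, VIF."""
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

from mesofish.io import ValidationError, ZotuTable
from mesofish.stats import (aggregate, dispersion_test, dissimilarity,
                            envfit, nmds, permanova, vif_screen)
from oracles import permanova_exact_p, permanova_f


class TestAggregate:
    def table(self):
        df = pd.DataFrame({"s1": [10, 5, 1, 0], "s2": [0, 0, 0, 7]},
                          index=["z1", "z2", "z3", "z4"])
        return ZotuTable(df)

    def test_counts_distinct_zotus(self):
        m = {"z1": "Serranidae", "z2": "Serranidae", "z3": "Serranidae",
             "z4": "Muraenidae"}
        out = aggregate(self.table(), m)
        assert out.loc["s1", "Serranidae"] == 3
        assert out.loc["s2", "Serranidae"] == 0
        assert out.loc["s2", "Muraenidae"] == 1

    def test_binary_view(self):
        m = {f"z{i}": "F" for i in range(1, 5)}
        out = aggregate(self.table(), m, binary=True)
        assert set(out.to_numpy().ravel()) <= {0, 1}

    def test_unmapped_zotu_rejected_unless_dropped(self):
        m = {"z1": "F", "z2": "F", "z3": "F"}
        with pytest.raises(ValidationError, match="unmapped"):
            aggregate(self.table(), m)
        out = aggregate(self.table(), m, drop_unmapped=True)
        assert "Muraenidae" not in out.columns


class TestDissimilarity:
    def test_identical_samples_zero(self):
        mat = pd.DataFrame([[3, 1, 0], [3, 1, 0]], index=["a", "b"])
        for index in ("jaccard", "bray_curtis"):
            assert dissimilarity(mat, index)["a", "b"] == 0.0

    def test_jaccard_two_thirds(self):
        mat = pd.DataFrame([[1, 1, 0], [1, 0, 1]], index=["a", "b"])
        assert dissimilarity(mat, "jaccard")["a", "b"] == pytest.approx(2 / 3)

    def test_bray_curtis_formula(self):
        mat = pd.DataFrame([[2, 0, 1], [1, 1, 1]], index=["a", "b"])
        assert dissimilarity(mat, "bray_curtis")["a", "b"] == \
            pytest.approx(2 / 6)

    def test_bray_curtis_all_zero_pair(self, caplog):
        mat = pd.DataFrame([[0, 0], [0, 0], [1, 2]], index=["a", "b", "c"])
        d = dissimilarity(mat, "bray_curtis")
        assert d["a", "b"] == 0.0

    def test_gower_mixed(self):
        df = pd.DataFrame({
            "depth": [70.0, 90.0, 110.0],
            "substrate": ["coral", "coral", "mud"],
        }, index=["a", "b", "c"])
        d = dissimilarity(df, "gower")
        # a-b: depth |70-90|/40 = 0.5, substrate 0 -> mean 0.25
        assert d["a", "b"] == pytest.approx(0.25)
        # a-c: depth 1.0, substrate 1 -> 1.0
        assert d["a", "c"] == pytest.approx(1.0)

    def test_gower_skips_missing(self):
        df = pd.DataFrame({
            "depth": [70.0, np.nan],
            "substrate": ["coral", "mud"],
        }, index=["a", "b"])
        d = dissimilarity(df, "gower")
        assert d["a", "b"] == pytest.approx(1.0)  # only substrate compared

    def test_jaccard_equals_bray_on_binary_equal_totals(self):
        mat = pd.DataFrame([[1, 1, 0, 0], [0, 1, 1, 0], [1, 0, 0, 1]],
                           index=list("abc"))
        dj = dissimilarity(mat, "jaccard")
        db = dissimilarity(mat, "bray_curtis")
        # equal totals & binary: J = 2BC / (1 + BC); here BC = 1/2, J = 2/3
        for pair in (("a", "b"), ("a", "c"), ("b", "c")):
            bc = db[pair]
            assert dj[pair] == pytest.approx(2 * bc / (1 + bc))

    def test_symmetry_and_identity(self, rng):
        mat = pd.DataFrame(rng.integers(0, 9, size=(6, 10)),
                           index=[f"s{i}" for i in range(6)])
        for index in ("jaccard", "bray_curtis"):
            d = dissimilarity(mat, index)
            assert np.allclose(d.data, d.data.T)
            assert np.all(np.diag(d.data) == 0)


class TestNmds:
    def test_equilateral_zero_stress(self):
        D = DistanceMatrix(np.ones((3, 3)) - np.eye(3), ids=list("abc"))
        res = nmds(D, k=2, n_restarts=5, seed=0)
        assert res.stress < 0.01

    def test_recovers_euclidean_configuration(self, rng):
        X = rng.normal(size=(12, 2))
        D = DistanceMatrix(
            np.sqrt(((X[:, None] - X[None, :]) ** 2).sum(-1)),
            ids=[f"s{i}" for i in range(12)])
        res = nmds(D, k=2, n_restarts=8, seed=3)
        assert res.stress < 0.01
        assert res.converged

    def test_deterministic_per_seed(self, rng):
        X = rng.random((8, 3))
        D = DistanceMatrix(
            np.sqrt(((X[:, None] - X[None, :]) ** 2).sum(-1)),
            ids=[f"s{i}" for i in range(8)])
        r1 = nmds(D, seed=5)
        r2 = nmds(D, seed=5)
        assert r1.stress == r2.stress
        pd.testing.assert_frame_equal(r1.coords, r2.coords)

    def test_coordinates_centered(self, rng):
        X = rng.random((9, 4))
        D = DistanceMatrix(
            np.sqrt(((X[:, None] - X[None, :]) ** 2).sum(-1)),
            ids=[f"s{i}" for i in range(9)])
        res = nmds(D, seed=1)
        assert np.allclose(res.coords.mean(axis=0), 0, atol=1e-9)


def two_group_matrix():
    D = np.array([[0.0, 0.1, 1.0, 1.0],
                  [0.1, 0.0, 1.0, 1.0],
                  [1.0, 1.0, 0.0, 0.1],
                  [1.0, 1.0, 0.1, 0.0]])
    dm = DistanceMatrix(D, ids=["a1", "a2", "b1", "b2"])
    groups = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
    return dm, groups


class TestPermanova:
    def test_hand_computed_F_and_R2(self):
        dm, groups = two_group_matrix()
        res = permanova(dm, groups, n_perm=99, seed=0)
        assert res.F == pytest.approx(199.0)
        assert res.R2 == pytest.approx(0.99005, abs=1e-5)
        assert res.df == (1, 2)

    def test_exact_enumeration_matches_bruteforce(self, rng):
        for n, sizes in ((6, (3, 3)), (7, (3, 4)), (8, (4, 4))):
            X = rng.random((n, n))
            D = (X + X.T) / 2
            np.fill_diagonal(D, 0)
            ids = [f"s{i}" for i in range(n)]
            labels = ["A"] * sizes[0] + ["B"] * sizes[1]
            dm = DistanceMatrix(D, ids=ids)
            res = permanova(dm, dict(zip(ids, labels)), n_perm=None)
            assert res.F == pytest.approx(permanova_f(D, labels))
            assert res.p == pytest.approx(permanova_exact_p(D, labels))

    def test_matches_scikit_bio(self, rng):
        from skbio.stats.distance import permanova as skbio_permanova
        X = rng.random((10, 10))
        D = (X + X.T) / 2
        np.fill_diagonal(D, 0)
        ids = [f"s{i}" for i in range(10)]
        labels = ["A"] * 5 + ["B"] * 5
        dm = DistanceMatrix(D, ids=ids)
        ours = permanova(dm, dict(zip(ids, labels)), n_perm=99, seed=0)
        ref = skbio_permanova(dm, grouping=labels, permutations=0)
        assert ours.F == pytest.approx(float(ref["test statistic"]))

    def test_matches_vegan_adonis2(self, rng, tmp_path):
        X = rng.random((9, 6))
        mat = pd.DataFrame(X, index=[f"s{i}" for i in range(9)])
        dm = dissimilarity(mat, "bray_curtis")
        labels = ["A"] * 4 + ["B"] * 5
        ours = permanova(dm, dict(zip(mat.index, labels)), n_perm=99)
        d_path = tmp_path / "d.tsv"
        pd.DataFrame(dm.data).to_csv(d_path, sep="\t", index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(vegan))
            d <- as.dist(as.matrix(read.delim("{d_path}")))
            g <- factor(c(rep("A", 4), rep("B", 5)))
            fit <- adonis2(d ~ g, permutations = 0)
            cat(fit$F[1], fit$R2[1], sep = "\\n")
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        f_ref, r2_ref = (float(x) for x in out.stdout.split())
        assert ours.F == pytest.approx(f_ref, rel=1e-6)
        assert ours.R2 == pytest.approx(r2_ref, rel=1e-6)

    def test_single_group_rejected(self):
        dm, _ = two_group_matrix()
        with pytest.raises(ValidationError):
            permanova(dm, {i: "A" for i in dm.ids})


class TestDispersion:
    def test_identical_groups_f_near_zero(self):
        D = np.array([[0.0, 1.0, 0.0, 1.0],
                      [1.0, 0.0, 1.0, 0.0],
                      [0.0, 1.0, 0.0, 1.0],
                      [1.0, 0.0, 1.0, 0.0]])
        dm = DistanceMatrix(D, ids=["a1", "a2", "b1", "b2"])
        res = dispersion_test(dm, {"a1": "A", "a2": "A",
                                   "b1": "B", "b2": "B"}, n_perm=99)
        assert res.F == pytest.approx(0.0, abs=1e-9)

    def test_contrast_detected(self, rng):
        tight = np.tile(rng.normal(size=(1, 3)), (6, 1)) + \
            rng.normal(scale=0.01, size=(6, 3))
        spread = rng.normal(scale=3.0, size=(6, 3))
        X = np.vstack([tight, spread])
        D = np.sqrt(((X[:, None] - X[None, :]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(12)]
        dm = DistanceMatrix(D, ids=ids)
        groups = {ids[i]: ("T" if i < 6 else "S") for i in range(12)}
        res = dispersion_test(dm, groups, n_perm=199, seed=1)
        assert res.F > 10 and res.p < 0.05

    def test_null_calibration(self, rng):
        high = 0
        n_sim = 200
        for s in range(n_sim):
            X = rng.normal(size=(12, 3))
            D = np.sqrt(((X[:, None] - X[None, :]) ** 2).sum(-1))
            ids = [f"s{i}" for i in range(12)]
            dm = DistanceMatrix(D, ids=ids)
            groups = {ids[i]: ("A" if i < 6 else "B") for i in range(12)}
            res = dispersion_test(dm, groups, n_perm=99, seed=s)
            high += res.p > 0.05
        assert high / n_sim >= 0.90

    def test_singleton_group_rejected(self):
        dm, _ = two_group_matrix()
        with pytest.raises(ValidationError, match="fewer than two"):
            dispersion_test(dm, {"a1": "A", "a2": "B", "b1": "B",
                                 "b2": "B"})


class TestEnvfit:
    def coords(self, rng, n=12):
        X = rng.normal(size=(n, 2))
        X -= X.mean(axis=0)
        return pd.DataFrame(X, index=[f"s{i}" for i in range(n)],
                            columns=["NMDS1", "NMDS2"])

    def test_axis_variable_r2_one(self, rng):
        coords = self.coords(rng)
        variables = pd.DataFrame({"v": coords["NMDS1"]})
        fit = envfit(coords, variables, n_perm=99)[0]
        assert fit.r2 == pytest.approx(1.0)
        assert abs(fit.direction[0]) == pytest.approx(1.0, abs=1e-6)

    def test_independent_variable_small_r2(self, rng):
        coords = self.coords(rng, n=40)
        r2s = []
        for _ in range(30):
            variables = pd.DataFrame({"v": rng.normal(size=40)},
                                     index=coords.index)
            r2s.append(envfit(coords, variables, n_perm=19)[0].r2)
        assert np.mean(r2s) < 0.2

    def test_factor_separating_axis(self, rng):
        n = 12
        X = np.zeros((n, 2))
        X[:6, 0] = -3 + rng.normal(scale=0.1, size=6)
        X[6:, 0] = 3 + rng.normal(scale=0.1, size=6)
        X[:, 1] = rng.normal(scale=0.1, size=n)
        coords = pd.DataFrame(X, index=[f"s{i}" for i in range(n)])
        variables = pd.DataFrame({"grp": ["x"] * 6 + ["y"] * 6},
                                 index=coords.index)
        fit = envfit(coords, variables, n_perm=99)[0]
        assert fit.kind == "factor" and fit.r2 > 0.95 and fit.p <= 0.05
        assert set(fit.centroids.index) == {"x", "y"}

    def test_constant_variable_zero(self, rng):
        coords = self.coords(rng)
        variables = pd.DataFrame({"c": np.ones(len(coords))},
                                 index=coords.index)
        fit = envfit(coords, variables, n_perm=19)[0]
        assert fit.r2 == 0.0


class TestVif:
    def orthonormal(self, rng, n, m):
        A = rng.normal(size=(n, m + 1))
        A -= A.mean(axis=0)
        Q, _ = np.linalg.qr(A)
        return Q[:, :m]

    def test_orthogonal_all_retained(self, rng):
        Q = self.orthonormal(rng, 30, 3)
        df = pd.DataFrame(Q, columns=["x1", "x2", "x3"])
        retained, vifs = vif_screen(df)
        assert retained == ["x1", "x2", "x3"]
        assert np.allclose(vifs.to_numpy(), 1.0, atol=1e-8)

    def test_perfect_collinearity_dropped(self, rng):
        x1 = rng.normal(size=25)
        df = pd.DataFrame({"x1": x1, "x2": 2 * x1,
                           "x3": rng.normal(size=25)})
        retained, _ = vif_screen(df)
        # x1/x2 tie at infinite VIF; the later column (x2) goes first
        assert retained == ["x1", "x3"]

    def test_equicorrelated_vif(self, rng):
        Q = self.orthonormal(rng, 40, 3)
        R = np.full((3, 3), 0.5)
        np.fill_diagonal(R, 1.0)
        X = Q @ np.linalg.cholesky(R).T
        df = pd.DataFrame(X, columns=["x1", "x2", "x3"])
        retained, vifs = vif_screen(df)
        assert retained == ["x1", "x2", "x3"]
        assert np.allclose(vifs.to_numpy(), 1.5, atol=1e-6)

    def test_categorical_one_hot(self, rng):
        df = pd.DataFrame({
            "depth": rng.normal(size=20),
            "substrate": rng.choice(["coral", "mud", "sand"], size=20),
        })
        retained, _ = vif_screen(df)
        assert retained == ["depth", "substrate"]
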