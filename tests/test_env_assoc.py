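"""PCA, representative selection, association, and site clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg, stats

from traitnet import (EnvTable, RunConfig, associate, cluster_sites, pca,
                      select_representatives)
from traitnet.synth import SynthConfig, generate_env, generate_study


def env_from(df: pd.DataFrame, block: str = "soil") -> EnvTable:
    return EnvTable(df.copy(), block)


class TestPCA:
    def test_two_perfectly_correlated_factors(self):
        x = np.arange(10.0)
        res = pca(env_from(pd.DataFrame({"SOM": x, "STK": 3 * x + 1},
                                        index=[f"T{i}" for i in range(10)])))
        assert res.explained_proportion.iloc[0] == pytest.approx(1.0)

    def test_orthogonal_equal_variance_factors(self):
        # factor correlation exactly 0 → both eigenvalues of the 2×2
        # correlation matrix are 1 → equal explained proportions
        df = pd.DataFrame({"SOM": [1.0, 1, -1, -1], "STK": [1.0, -1, 1, -1]},
                          index=list("abcd"))
        res = pca(env_from(df))
        np.testing.assert_allclose(res.explained_proportion, [0.5, 0.5])

    def test_matches_independent_eigensolver(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame(rng.normal(size=(20, 11)),
                          columns=[f"f{i}" for i in range(11)],
                          index=[f"T{i}" for i in range(20)])
        res = pca(env_from(df))
        corr = np.corrcoef((df - df.mean()).div(df.std()).to_numpy(), rowvar=False)
        want = np.sort(linalg.eigvals(corr).real)[::-1]
        np.testing.assert_allclose(res.explained_proportion.to_numpy(),
                                   want / want.sum(), atol=1e-10)
        # loadings are unit-norm eigenvectors
        np.testing.assert_allclose(
            np.linalg.norm(res.loadings.to_numpy(), axis=0), 1.0, atol=1e-10)

    def test_reconstruction_with_all_components(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(15, 6)),
                          columns=[f"f{i}" for i in range(6)],
                          index=[f"T{i}" for i in range(15)])
        res = pca(env_from(df))
        Z = ((df - df.mean()) / df.std()).to_numpy()
        np.testing.assert_allclose(
            res.scores.to_numpy() @ res.loadings.to_numpy().T, Z, atol=1e-10)

    def test_explained_invariant_to_factor_order(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(12, 5)),
                          columns=list("abcde"), index=[f"T{i}" for i in range(12)])
        a = pca(env_from(df)).explained_proportion.to_numpy()
        b = pca(env_from(df[list("ecadb")])).explained_proportion.to_numpy()
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_constant_factor_dropped_with_warning(self):
        df = pd.DataFrame({"SOM": [1.0, 2, 3, 4], "pH": [7.0] * 4,
                           "STK": [4.0, 3, 2, 1]}, index=list("abcd"))
        with pytest.warns(UserWarning, match="pH"):
            res = pca(env_from(df))
        assert "pH" not in res.loadings.index

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.normal(size=(10, 4)), columns=list("wxyz"),
                          index=[f"T{i}" for i in range(10)])
        res = pca(env_from(df))
        for comp in res.loadings.columns:
            col = res.loadings[comp]
            assert col.iloc[np.argmax(np.abs(col.to_numpy()))] > 0


class TestRepresentatives:
    def test_planted_blocks_one_rep_each(self):
        """Three orthogonal factor blocks: greedy |loading| selection returns
        one factor per planted block."""
        cfg = SynthConfig(env_noise_sd=0.15)
        for seed in range(5):
            climate, soil, cblocks, sblocks = generate_env(cfg, seed)
            reps = select_representatives(pca(soil), 3)
            assert len({sblocks[r] for r in reps}) == 3
            reps_c = select_representatives(pca(climate), 3)
            assert len({cblocks[r] for r in reps_c}) == 3

    def test_single_factor_table(self):
        df = pd.DataFrame({"SOM": [1.0, 2, 4, 3], "STK": [2.0, 4, 8, 6.1]},
                          index=list("abcd"))
        res = pca(env_from(df))
        assert select_representatives(res, 1) in (["SOM"], ["STK"])

    def test_too_many_components_rejected(self):
        df = pd.DataFrame({"SOM": [1.0, 2, 4], "STK": [2.0, 1, 4]},
                          index=list("abc"))
        with pytest.raises(ValueError):
            select_representatives(pca(env_from(df)), 5)

    def test_per_component_multiple_no_repeats(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(20, 8)),
                          columns=[f"f{i}" for i in range(8)],
                          index=[f"T{i}" for i in range(20)])
        reps = select_representatives(pca(env_from(df)), 3, per_component=2)
        assert len(reps) == 6 and len(set(reps)) == 6


class TestAssociate:
    def make_params(self, values: dict, sites) -> pd.DataFrame:
        return pd.DataFrame(values, index=pd.Index(sites, name="site"))

    def test_parameter_identical_to_factor(self):
        sites = [f"T{i}" for i in range(10)]
        x = np.linspace(0, 1, 10)
        env = env_from(pd.DataFrame({"SOM": x}, index=sites))
        params = self.make_params({"modularity": x}, sites)
        out = associate(params, env, ["SOM"])
        row = out.iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["p"] == pytest.approx(0.0, abs=1e-12)
        assert bool(row["significant"])

    def test_negative_association_limit(self):
        rng = np.random.default_rng(0)
        sites = [f"T{i}" for i in range(12)]
        x = np.linspace(0, 1, 12)
        env = env_from(pd.DataFrame({"STK": x}, index=sites))
        params = self.make_params(
            {"modularity": -x + 1e-6 * rng.standard_normal(12)}, sites)
        row = associate(params, env, ["STK"]).iloc[0]
        assert row["r"] == pytest.approx(-1.0, abs=1e-4)
        assert row["slope"] == pytest.approx(-1.0, abs=1e-3)

    def test_zero_variance_pair_skipped(self):
        sites = list("abcd")
        env = env_from(pd.DataFrame({"SOM": [1.0, 1, 1, 1],
                                     "STK": [1.0, 2, 3, 4]}, index=sites))
        params = self.make_params({"modularity": [0.1, 0.2, 0.3, 0.4]}, sites)
        with pytest.warns(UserWarning, match="zero variance"):
            out = associate(params, env, ["SOM", "STK"])
        assert list(out["factor"]) == ["STK"]

    def test_planted_coupling_recovered_in_sampling_interval(self):
        """corr(modularity, STK) planted at −0.6 over 20 sites: the mean
        estimate over 200 replicates sits inside the 95% sampling band."""
        rng = np.random.default_rng(42)
        rs = []
        rho = -0.6
        for _ in range(200):
            z = rng.standard_normal((20, 2))
            stk = z[:, 0]
            modu = rho * stk + np.sqrt(1 - rho**2) * z[:, 1]
            sites = [f"T{i}" for i in range(20)]
            env = env_from(pd.DataFrame({"STK": stk}, index=sites))
            params = self.make_params({"modularity": modu}, sites)
            rs.append(associate(params, env, ["STK"]).iloc[0]["r"])
        # Fisher-z sampling sd at n=20 is ~1/sqrt(17); mean of 200 reps
        se = 1 / np.sqrt(17) / np.sqrt(200)
        assert np.tanh(np.mean(np.arctanh(rs))) == pytest.approx(rho, abs=4 * se + 0.02)

    def test_pvalues_uniform_under_null(self):
        """KS check: association p-values on independent data are U(0,1)."""
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(1000):
            x, y = rng.standard_normal((2, 20))
            ps.append(stats.linregress(x, y).pvalue)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestClusterSites:
    def test_planted_groups_recovered(self):
        rng = np.random.default_rng(1)
        sites = [f"T{i}" for i in range(12)]
        base = np.zeros((12, 5))
        base[6:] += 8.0  # two well-separated groups
        clim = pd.DataFrame(base + rng.normal(scale=0.3, size=(12, 5)),
                            columns=[f"BIO{i+1}" for i in range(5)], index=sites)
        soil = pd.DataFrame(base[:, :3] + rng.normal(scale=0.3, size=(12, 3)),
                            columns=["SOM", "STK", "SWC"], index=sites)
        out = cluster_sites(env_from(clim, "climate"), env_from(soil, "soil"), k=2)
        labels = out.labels.to_numpy()
        assert len(set(labels[:6])) == 1 and len(set(labels[6:])) == 1
        assert labels[0] != labels[-1]
        assert out.linkage_matrix.shape == (11, 4)

    def test_ward_heights_match_hand_agglomeration(self):
        """5 points in the plane: linkage heights equal a naive Ward (D2)
        agglomeration computed from scratch."""
        pts = np.array([[0.0, 0], [0, 1], [4, 0], [4, 1], [10, 0]])
        sites = list("abcde")
        clim = pd.DataFrame({"BIO1": pts[:, 0], "BIO2": pts[:, 1]}, index=sites)
        soil = pd.DataFrame({"SOM": np.zeros(5) + [0, .1, .2, .3, .4]}, index=sites)
        X = np.column_stack([
            (pts[:, 0] - pts[:, 0].mean()) / pts[:, 0].std(ddof=1),
            (pts[:, 1] - pts[:, 1].mean()) / pts[:, 1].std(ddof=1),
            (soil["SOM"] - soil["SOM"].mean()) / soil["SOM"].std(ddof=1),
        ])

        # naive Ward: merge the pair minimising the ESS increase; height is
        # sqrt(2 · ΔESS), the Ward.D2 convention
        clusters = [[i] for i in range(5)]
        heights = []
        while len(clusters) > 1:
            best = None
            for i in range(len(clusters)):
                for j in range(i + 1, len(clusters)):
                    a, b = X[clusters[i]], X[clusters[j]]
                    na, nb = len(a), len(b)
                    d2 = ((a.mean(0) - b.mean(0)) ** 2).sum()
                    delta = na * nb / (na + nb) * d2
                    if best is None or delta < best[0]:
                        best = (delta, i, j)
            delta, i, j = best
            heights.append(np.sqrt(2 * delta))
            clusters[i] = clusters[i] + clusters[j]
            del clusters[j]

        out = cluster_sites(env_from(clim, "climate"), env_from(soil, "soil"), k=2)
        np.testing.assert_allclose(np.sort(out.linkage_matrix[:, 2]),
                                   np.sort(heights), atol=1e-10)

    def test_k_exceeding_sites_rejected(self, default_study):
        _, climate, soil, _ = default_study
        with pytest.raises(ValueError):
            cluster_sites(climate, soil, k=21)

    def test_identical_sites_degenerate_split(self):
        sites = list("abcd")
        clim = pd.DataFrame({"BIO1": [1.0] * 4, "BIO2": [2.0] * 4}, index=sites)
        soil = pd.DataFrame({"SOM": [3.0] * 4}, index=sites)
        out = cluster_sites(env_from(clim, "climate"), env_from(soil, "soil"), k=2)
        assert set(out.labels) <= {1, 2}

    def test_study_clustering_is_deterministic(self, default_study):
        _, climate, soil, _ = default_study
        a = cluster_sites(climate, soil, k=2)
        b = cluster_sites(climate, soil, k=2)
        pd.testing.assert_series_equal(a.labels, b.labels)
        assert set(a.labels) == {1, 2}
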