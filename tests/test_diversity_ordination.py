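import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import braycurtis as scipy_braycurtis

from rumenamp.diversity_ordination import (
    alpha_indices,
    alpha_table,
    bray_curtis,
    cca,
    pcoa,
    rarefy,
)

from ._oracles import bray_curtis_oracle


class TestRarefy:
    def test_exact_depth_sample_unchanged(self):
        counts = pd.DataFrame({"s1": [900, 600, 300]})
        out = rarefy(counts, depth=1800, seed=0)
        assert out["s1"].tolist() == [900, 600, 300]

    def test_column_sums_equal_depth(self, rng):
        counts = pd.DataFrame(rng.integers(0, 100, size=(40, 5)) + 10)
        out = rarefy(counts, depth=500, seed=3)
        assert (out.sum(axis=0) == 500).all()
        assert (out <= counts).all().all()  # without replacement

    def test_under_depth_sample_named(self):
        counts = pd.DataFrame({"tiny": [5, 5]})
        with pytest.raises(ValueError, match="tiny"):
            rarefy(counts, depth=1800)

    def test_deterministic_given_seed(self, rng):
        counts = pd.DataFrame(rng.integers(0, 80, size=(30, 3)) + 10)
        a = rarefy(counts, depth=400, seed=11)
        b = rarefy(counts, depth=400, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_hypergeometric_mean(self):
        # OTU with 900 of 3600 reads rarefied to 1800: E[count] = 450
        counts = pd.DataFrame({"s": [900, 2700]})
        draws = np.array([
            rarefy(counts, depth=1800, seed=s).iloc[0, 0] for s in range(1000)
        ])
        var = 1800 * 0.25 * 0.75 * (3600 - 1800) / (3600 - 1)
        se = np.sqrt(var / 1000)
        assert abs(draws.mean() - 450) < 3 * se


class TestAlphaIndices:
    def test_even_four_otu_sample(self):
        a = alpha_indices([450, 450, 450, 450])
        assert a.observed_otus == 4
        assert a.shannon == pytest.approx(np.log(4), abs=1e-12)
        assert a.simpson == pytest.approx(4 * 450 * 449 / (1800 * 1799), abs=1e-12)
        assert a.chao1 == 4  # no singletons
        assert a.coverage == 1.0

    def test_single_otu_extremes(self):
        a = alpha_indices([100])
        assert a.shannon == 0.0
        assert a.simpson == 1.0

    def test_chao1_with_singletons_and_doubletons(self):
        # F1=2, F2=1 -> chao1 = S_obs + 2*1/(2*2) = S_obs + 0.5
        a = alpha_indices([10, 10, 2, 1, 1])
        assert a.chao1 == 5 + 0.5

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            alpha_indices([0, 0, 0])

    def test_invariant_to_otu_ordering(self, rng):
        counts = rng.integers(0, 30, size=50)
        counts[0] = 5
        a = alpha_indices(counts)
        b = alpha_indices(counts[::-1].copy())
        assert (a.chao1, a.observed_otus, a.shannon, a.simpson, a.coverage) == (
            b.chao1, b.observed_otus, b.shannon, b.simpson, b.coverage
        )

    def test_table_shape(self, rng):
        counts = pd.DataFrame(rng.integers(1, 30, size=(20, 4)))
        table = alpha_table(counts)
        assert list(table.columns) == [
            "chao1", "observed_otus", "shannon", "simpson", "coverage"
        ]
        assert len(table) == 4


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        m = pd.DataFrame([[3, 5, 2], [3, 5, 2]])
        assert bray_curtis(m).iloc[0, 1] == 0.0

    def test_disjoint_samples_one(self):
        m = pd.DataFrame([[5, 0, 3, 0], [0, 2, 0, 7]])
        assert bray_curtis(m).iloc[0, 1] == 1.0

    def test_matches_bruteforce_oracle(self, rng):
        m = pd.DataFrame(rng.integers(0, 30, size=(5, 20)))
        d = bray_curtis(m)
        for i in range(5):
            for j in range(5):
                expected = bray_curtis_oracle(list(m.iloc[i]), list(m.iloc[j]))
                assert d.iloc[i, j] == pytest.approx(expected)

    def test_matches_scipy(self, rng):
        m = pd.DataFrame(rng.integers(0, 30, size=(4, 15)).astype(float))
        d = bray_curtis(m)
        for i in range(4):
            for j in range(i + 1, 4):
                assert d.iloc[i, j] == pytest.approx(
                    scipy_braycurtis(m.iloc[i], m.iloc[j])
                )

    def test_metric_properties(self, rng):
        m = pd.DataFrame(rng.integers(0, 40, size=(6, 12)) + 1)
        d = bray_curtis(m).to_numpy()
        assert np.allclose(np.diag(d), 0.0)
        assert np.allclose(d, d.T)
        assert ((d >= 0) & (d <= 1)).all()


class TestPcoa:
    def test_three_equidistant_points(self):
        d = pd.DataFrame(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float))
        ordn = pcoa(d)
        assert len(ordn.eigenvalues) == 2
        assert ordn.eigenvalues[0] == pytest.approx(ordn.eigenvalues[1])

    def test_euclidean_reconstruction(self, rng):
        pts = rng.normal(size=(8, 2))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        ordn = pcoa(pd.DataFrame(d))
        coords = ordn.site_coords.to_numpy()
        back = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        assert np.abs(back - d).max() < 1e-8
        assert ordn.negative_eigenvalues.size == 0

    def test_sign_convention_deterministic(self, rng):
        pts = rng.normal(size=(6, 3))
        d = pd.DataFrame(np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)))
        a, b = pcoa(d), pcoa(d)
        pd.testing.assert_frame_equal(a.site_coords, b.site_coords)
        for k in range(a.site_coords.shape[1]):
            col = a.site_coords.iloc[:, k].to_numpy()
            assert col[np.argmax(np.abs(col))] > 0

    def test_asymmetric_rejected(self):
        d = pd.DataFrame([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError):
            pcoa(d)

    def test_proportions_sum_to_at_most_one(self, rng):
        m = pd.DataFrame(rng.integers(0, 30, size=(6, 25)) + 1)
        ordn = pcoa(bray_curtis(m))
        assert ordn.proportion_explained.sum() <= 1.0 + 1e-9


def _toy_species(rng=None):
    return pd.DataFrame(
        [[12, 3, 1, 0, 2, 5], [8, 6, 3, 1, 4, 2], [2, 9, 7, 5, 3, 1],
         [1, 4, 9, 11, 2, 3]],
        index=["s1", "s2", "s3", "s4"],
    )


class TestCca:
    def test_total_inertia_is_scaled_chi_square(self):
        y = _toy_species()
        env = pd.DataFrame({"grad": [1.0, 2.0, 3.0, 4.0],
                            "other": [2.0, 1.0, 4.0, 3.0]}, index=y.index)
        ordn = cca(y, env)
        obs = y.to_numpy(dtype=float)
        total = obs.sum()
        expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
        chi_square = ((obs - expected) ** 2 / expected).sum()
        assert ordn.total_inertia == pytest.approx(chi_square / total)
        assert ordn.constrained_inertia <= ordn.total_inertia + 1e-12

    def test_perfect_gradient_axis_correlation(self, rng):
        # community turnover follows one covariate exactly
        n, m = 10, 15
        grad = np.linspace(0, 1, n)
        centers = np.linspace(0, 1, m)
        y = np.exp(-((grad[:, None] - centers[None, :]) ** 2) / 0.02) * 50
        species = pd.DataFrame(np.round(y).astype(int) + 1)
        env = pd.DataFrame({"grad": grad, "noise": rng.normal(size=n)})
        ordn = cca(species, env)
        r = np.corrcoef(ordn.site_coords.iloc[:, 0], grad)[0, 1]
        assert abs(r) > 0.99

    def test_permuted_env_has_null_level_inertia(self, rng):
        n, m = 12, 20
        grad = np.linspace(0, 1, n)
        centers = np.linspace(0, 1, m)
        y = np.exp(-((grad[:, None] - centers[None, :]) ** 2) / 0.02) * 40
        species = pd.DataFrame(np.round(y).astype(int) + 1)
        real = cca(species, pd.DataFrame({"grad": grad})).constrained_inertia
        null = []
        for _ in range(99):
            null.append(
                cca(species, pd.DataFrame({"grad": rng.permutation(grad)}))
                .constrained_inertia
            )
        null = np.array(null)
        assert real > np.quantile(null, 0.99)  # signal beats the null
        # and a permuted covariate sits inside its own null spread
        assert null.min() < np.median(null) * 0.9 or null.max() < real

    def test_constant_covariate_rejected(self):
        y = _toy_species()
        env = pd.DataFrame({"flat": [1.0, 1.0, 1.0, 1.0]}, index=y.index)
        with pytest.raises(ValueError, match="constant"):
            cca(y, env)

    def test_collinear_covariate_named(self):
        y = _toy_species()
        env = pd.DataFrame({
            "a": [1.0, 2.0, 3.0, 4.0],
            "b": [2.0, 4.0, 6.0, 8.0],  # 2*a
        }, index=y.index)
        with pytest.raises(ValueError, match="b"):
            cca(y, env)

    def test_too_many_covariates_rejected(self, rng):
        y = _toy_species()
        env = pd.DataFrame(rng.normal(size=(4, 4)), index=y.index)
        with pytest.raises(ValueError):
            cca(y, env)

    def test_inertia_monotone_in_covariates(self, rng):
        n, m = 10, 18
        species = pd.DataFrame(rng.integers(1, 30, size=(n, m)))
        env = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
        inertias = [
            cca(species, env[cols]).constrained_inertia
            for cols in (["a"], ["a", "b"], ["a", "b", "c"])
        ]
        assert inertias[0] <= inertias[1] + 1e-10 <= inertias[2] + 2e-10

    def test_biplot_arrow_shape(self, rng):
        y = _toy_species()
        env = pd.DataFrame({"grad": [1.0, 2.0, 3.0, 4.0],
                            "other": [2.0, 1.0, 4.0, 3.0]}, index=y.index)
        ordn = cca(y, env)
        assert list(ordn.biplot_arrows.index) == ["grad", "other"]
        assert ordn.species_coords.shape[0] == y.shape[1]
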