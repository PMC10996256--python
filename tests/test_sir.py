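import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

import sirtest as st
from sirtest import ValidationError
from sirtest.sir import (
    compute_grm,
    estimate_directions,
    make_plan,
    pooled_within_cov,
    slice_by_relatedness,
    slice_exhaustive,
    slice_moments,
    standardize,
)


def _random_dataset(seed, n=80, k=3, q=4, rho=0.4):
    rng = np.random.default_rng(seed)
    G = st.simulate_genotypes(n, k, rng=rng)
    Y = st.simulate_phenotypes(G, np.zeros((k, q)), rho, rng)
    return Y, G


class TestStandardize:
    def test_single_trait_mle_scaling(self):
        Y = np.array([[1.0], [2.0], [3.0]])
        Z, T = standardize(Y)
        # mean 2, MLE sd sqrt(2/3)
        np.testing.assert_allclose(Z.ravel(), [-np.sqrt(1.5), 0.0, np.sqrt(1.5)])
        assert T.mean[0] == pytest.approx(2.0)

    def test_whitening_property(self):
        Y, _ = _random_dataset(1)
        Z, T = standardize(Y)
        n = Z.shape[0]
        np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(Z.T @ Z / n, np.eye(Z.shape[1]), atol=1e-8)
        np.testing.assert_allclose(T.inv_sqrt @ T.cov @ T.inv_sqrt, np.eye(Z.shape[1]), atol=1e-8)

    def test_duplicated_column_is_singular(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=(50, 1))
        Y = np.column_stack([y, y])
        with pytest.raises(ValidationError, match="singular"):
            standardize(Y)

    def test_requires_more_samples_than_traits(self):
        with pytest.raises(ValidationError, match="n > q"):
            standardize(np.zeros((3, 3)))


class TestSlicing:
    def test_exhaustive_counts_k1(self):
        G = st.GenotypeMatrix(np.array([[0], [0], [1], [2], [2], [2]]),
                              [f"s{i}" for i in range(6)], ["a"])
        plan = slice_exhaustive(G)
        assert plan.H == 3
        np.testing.assert_allclose(sorted(plan.proportions), [1 / 6, 1 / 3, 1 / 2])
        assert plan.proportions.sum() == 1.0

    def test_all_nine_patterns_k2(self):
        pats = np.array([[a, b] for a in range(3) for b in range(3)])
        G = st.GenotypeMatrix(np.vstack([pats, pats]), [f"s{i}" for i in range(18)], ["a", "b"])
        assert slice_exhaustive(G).H == 9

    def test_degenerate_single_pattern(self):
        G = st.GenotypeMatrix(np.ones((5, 2), dtype=int), [f"s{i}" for i in range(5)], ["a", "b"])
        plan = slice_exhaustive(G)
        assert plan.H == 1 and plan.proportions[0] == 1.0

    def test_cap_exceeded_directs_to_relatedness(self):
        rng = np.random.default_rng(0)
        G = st.simulate_genotypes(30, 11, rng=rng)
        with pytest.raises(ValidationError, match="relatedness"):
            slice_exhaustive(G)

    def test_relatedness_exact_blocks(self):
        _, G = _random_dataset(3, n=100, k=6)
        plan = slice_by_relatedness(G, target_slice_size=10, min_slice_size=5)
        assert plan.H == 10
        assert all(np.bincount(plan.assignment) == 10)

    def test_relatedness_merges_small_remainder(self):
        _, G = _random_dataset(4, n=13, k=6)
        plan = slice_by_relatedness(G, target_slice_size=10, min_slice_size=5)
        # remainder block of 3 < 5 is merged into the block of 10
        assert plan.H == 1 and np.bincount(plan.assignment)[0] == 13

    @pytest.mark.parametrize("n", [17, 23, 51, 104])
    def test_relatedness_min_slice_size_holds(self, n):
        _, G = _random_dataset(n, n=n, k=8)
        plan = slice_by_relatedness(G)
        assert np.bincount(plan.assignment).min() >= 5
        assert plan.proportions.sum() == pytest.approx(1.0, abs=1e-12)

    def test_relatedness_too_few_samples(self):
        _, G = _random_dataset(5, n=8, k=6)
        with pytest.raises(ValidationError):
            slice_by_relatedness(G, min_slice_size=5)


class TestGRM:
    def test_identical_rows_correlate_perfectly(self):
        G = st.GenotypeMatrix(np.array([[0, 1, 2], [0, 1, 2], [2, 1, 0]]),
                              ["a", "b", "c"], ["x", "y", "z"])
        grm = compute_grm(G)
        assert grm.values[0, 1] == pytest.approx(1.0)
        assert grm.values[0, 2] == pytest.approx(-1.0)
        np.testing.assert_allclose(np.diag(grm.values), 1.0)

    def test_bounds_and_symmetry(self):
        _, G = _random_dataset(6, n=40, k=20)
        assert G.values.std(axis=1).min() > 0  # fixture has no constant rows
        grm = compute_grm(G)
        assert np.all(np.abs(grm.values) <= 1.0 + 1e-12)
        np.testing.assert_allclose(grm.values, grm.values.T)

    def test_constant_individual_named_in_error(self):
        G = st.GenotypeMatrix(np.array([[1, 1, 1], [0, 1, 2]]), ["flat", "ok"], ["x", "y", "z"])
        with pytest.raises(ValidationError, match="flat"):
            compute_grm(G)


class TestMomentsAndPooling:
    def test_singleton_slice_has_zero_covariance(self):
        Z = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        plan = st.SlicingPlan(np.array([0, 1, 1]), 2, np.array([1 / 3, 2 / 3]), "exhaustive")
        means, covs = slice_moments(Z, plan)
        np.testing.assert_array_equal(covs[0], np.zeros((2, 2)))

    def test_single_slice_recovers_identity(self):
        Y, G = _random_dataset(7)
        Z, _ = standardize(Y)
        plan = st.SlicingPlan(np.zeros(Z.shape[0], dtype=int), 1, np.array([1.0]), "exhaustive")
        means, covs = slice_moments(Z, plan)
        np.testing.assert_allclose(covs[0], np.eye(Z.shape[1]), atol=1e-8)

    def test_equal_covs_pool_to_same(self):
        C = np.array([[2.0, 0.5], [0.5, 1.0]])
        E = pooled_within_cov([C, C, C], np.array([0.2, 0.3, 0.5]))
        np.testing.assert_allclose(E, C)

    @pytest.mark.parametrize("strategy", ["exhaustive", "relatedness"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_total_covariance_conservation(self, strategy, seed):
        """Pooled-within + proportion-weighted between covariance = identity."""
        Y, G = _random_dataset(seed, n=90, k=4, q=5)
        Z, _ = standardize(Y)
        plan = make_plan(G, st.RunConfig(slicing=strategy))
        means, covs = slice_moments(Z, plan)
        E = pooled_within_cov(covs, plan.proportions)
        between = (means * plan.proportions[:, None]).T @ means
        np.testing.assert_allclose(E + between, np.eye(5), atol=1e-8)
        w = np.linalg.eigvalsh(E)
        assert w.min() >= -1e-10 and w.max() <= 1 + 1e-8


class TestDirectionsAndReduce:
    def test_identity_pooled_cov_gives_unit_spectrum(self):
        Y, _ = _random_dataset(9)
        _, T = standardize(Y)
        est = estimate_directions(np.eye(4), T, d0=1)
        np.testing.assert_allclose(est.eigenvalues, 1.0)
        assert est.directions.shape == (1, 4)

    def test_oracle_pooled_cov_k1(self):
        """For k=1 exhaustive slices, Ê equals a brute-force pooled
        within-genotype covariance."""
        Y, G = _random_dataset(10, n=200, k=1, q=4)
        cfg = st.RunConfig()
        est = st.reduce(Y, G, cfg)
        Z, _ = standardize(Y)
        g = G.values.ravel()
        brute = np.zeros((4, 4))
        for val in np.unique(g):
            Zh = Z[g == val]
            C = Zh - Zh.mean(axis=0)
            brute += (len(Zh) / len(g)) * (C.T @ C / len(Zh))
        np.testing.assert_allclose(est.pooled_cov, brute, atol=1e-10)

    @pytest.mark.parametrize("seed", [0, 3])
    def test_affine_invariance_of_reduced_trait(self, seed):
        """ỹ is invariant up to sign/scale under invertible linear maps of Y."""
        Y, G = _random_dataset(seed, n=120, k=3, q=4)
        rng = np.random.default_rng(seed + 100)
        A = rng.normal(size=(4, 4)) + 4 * np.eye(4)
        Y2 = st.PhenotypeMatrix(Y.values @ A.T, Y.sample_ids, Y.trait_ids)
        cfg = st.RunConfig()
        y1 = st.reduce(Y, G, cfg).reduced_trait
        y2 = st.reduce(Y2, G, cfg).reduced_trait
        c = np.corrcoef(y1, y2)[0, 1]
        assert abs(c) > 1 - 1e-8

    def test_reduce_is_deterministic(self, signal_dataset):
        Y, G = signal_dataset
        cfg = st.RunConfig(seed=5)
        e1, e2 = st.reduce(Y, G, cfg), st.reduce(Y, G, cfg)
        np.testing.assert_array_equal(e1.reduced_trait, e2.reduced_trait)
        np.testing.assert_array_equal(e1.directions, e2.directions)

    def test_joint_row_permutation_equivariance(self, signal_dataset):
        Y, G = signal_dataset
        rng = np.random.default_rng(11)
        perm = rng.permutation(Y.n)
        ids = [Y.sample_ids[i] for i in perm]
        Yp = st.PhenotypeMatrix(Y.values[perm], ids, Y.trait_ids)
        Gp = st.GenotypeMatrix(G.values[perm], ids, G.snp_ids)
        cfg = st.RunConfig()
        e1, e2 = st.reduce(Y, G, cfg), st.reduce(Yp, Gp, cfg)
        np.testing.assert_allclose(e1.pooled_cov, e2.pooled_cov, atol=1e-12)
        np.testing.assert_allclose(np.abs(e1.reduced_trait[perm]),
                                   np.abs(e2.reduced_trait), atol=1e-10)

    def test_smoke_scenario1_end_to_end(self, signal_dataset):
        Y, G = signal_dataset
        est = st.reduce(Y, G, st.RunConfig())
        assert np.isfinite(est.reduced_trait).all()
        assert est.directions.shape == (1, Y.q)

    def test_direction_sign_is_deterministic(self, signal_dataset):
        Y, G = signal_dataset
        est = st.reduce(Y, G, st.RunConfig())
        # flipping all traits flips nothing observable: same |ỹ|
        Yf = st.PhenotypeMatrix(-Y.values, Y.sample_ids, Y.trait_ids)
        est2 = st.reduce(Yf, G, st.RunConfig())
        np.testing.assert_allclose(np.abs(est.reduced_trait),
                                   np.abs(est2.reduced_trait), atol=1e-10)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=hst.integers(0, 10_000),
       strategy=hst.sampled_from(["exhaustive", "relatedness"]))
def test_conservation_identity_property(seed, strategy):
    """Ê + Σ_h p̂_h z̄_h z̄_hᵀ = I for any dataset and slicing plan."""
    Y, G = _random_dataset(seed, n=60, k=4, q=3)
    est = st.reduce(Y, G, st.RunConfig(slicing=strategy))
    between = (est.slice_means * est.proportions[:, None]).T @ est.slice_means
    np.testing.assert_allclose(est.pooled_cov + between, np.eye(3), atol=1e-8)
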