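import numpy as np
import pandas as pd
import pytest
from scipy import stats

from popstruct import roh, simdata, structure
from popstruct.genio import MISSING, GenotypeMatrix
from popstruct.structure import (
    AncestryCutoff,
    ancestry_cutoff_filter,
    compute_pca,
    jitter_coordinates,
    mean_nonzero_test,
    nagelkerke_r2,
    nearest_neighbor_outliers,
    patterson_normalize,
    pc_geography_regression,
    project_samples,
    variance_share,
)

from conftest import random_genotypes


class TestPattersonNormalize:
    def test_hand_computed_3x2(self):
        geno = GenotypeMatrix(
            np.array([[0, 2], [1, 1], [2, 0]], dtype=np.int8),
            ["a", "b", "c"], ["s", "t"],
        )
        normalized, mu, scale = patterson_normalize(geno)
        # column sums 3 of 6 alleles; p_hat = (1+3)/(2+6) = 0.5; s = 0.5; mu = 1
        np.testing.assert_allclose(mu, [1.0, 1.0])
        np.testing.assert_allclose(scale, [0.5, 0.5])
        np.testing.assert_allclose(normalized, [[-2, 2], [0, 0], [2, -2]])

    def test_identical_heterozygotes_center_to_zero(self):
        geno = GenotypeMatrix(
            np.ones((4, 1), dtype=np.int8), list("abcd"), ["s"]
        )
        normalized, _, _ = patterson_normalize(geno)
        np.testing.assert_allclose(normalized, 0.0)

    def test_nonmissing_mean_zero(self):
        rng = np.random.default_rng(0)
        geno = random_genotypes(rng, 50, 30, missing=0.1)
        normalized, _, _ = patterson_normalize(geno)
        obs = geno.values != MISSING
        for j in range(30):
            assert normalized[obs[:, j], j].mean() == pytest.approx(0.0, abs=1e-12)

    def test_all_missing_column_rejected(self):
        geno = GenotypeMatrix(
            np.full((3, 1), MISSING, dtype=np.int8), list("abc"), ["s"]
        )
        with pytest.raises(ValueError, match="missing"):
            patterson_normalize(geno)


class TestComputePca:
    def test_separates_divergent_subpops(self, two_pop_cohort):
        (geno, _, _, _), _ = two_pop_cohort
        model = compute_pca(geno, k=5)
        labels = np.array([0] * 60 + [1] * 60)
        r = np.corrcoef(model.sample_scores[:, 0], labels)[0, 1]
        assert abs(r) > 0.9

    def test_eigenvalues_match_dense_oracle(self):
        rng = np.random.default_rng(1)
        geno = random_genotypes(rng, 100, 300)
        model = compute_pca(geno, k=10)
        normalized, _, _ = patterson_normalize(geno)
        s = np.linalg.svd(normalized, compute_uv=False)
        np.testing.assert_allclose(
            model.eigenvalues, s[:10] ** 2 / (100 - 1), rtol=1e-10
        )

    def test_duplicate_rows_identical_scores(self):
        rng = np.random.default_rng(2)
        base = random_genotypes(rng, 30, 100)
        values = np.vstack([base.values, base.values[:1]])
        geno = GenotypeMatrix(
            values, base.sample_ids + ["dup"], base.snp_ids
        )
        model = compute_pca(geno, k=3)
        np.testing.assert_allclose(
            model.sample_scores[0], model.sample_scores[-1], atol=1e-8
        )

    def test_scores_equal_normalized_times_weights(self):
        rng = np.random.default_rng(3)
        geno = random_genotypes(rng, 40, 120)
        model = compute_pca(geno, k=5)
        normalized, _, _ = patterson_normalize(geno)
        np.testing.assert_allclose(
            model.sample_scores, normalized @ model.snp_weights, atol=1e-8
        )

    def test_eigenvalue_sum_equals_total_variance_full_rank(self):
        rng = np.random.default_rng(4)
        geno = random_genotypes(rng, 20, 60)
        normalized, _, _ = patterson_normalize(geno)
        k = np.linalg.matrix_rank(normalized)
        model = compute_pca(geno, k=k)
        total_var = (normalized**2).sum() / (20 - 1)
        assert model.eigenvalues.sum() == pytest.approx(total_var, rel=1e-6)

    def test_k_exceeding_rank_rejected(self):
        geno = GenotypeMatrix(
            np.array([[0, 0], [1, 1], [2, 2], [1, 1]], dtype=np.int8),
            list("abcd"), ["s", "t"],
        )
        with pytest.raises(ValueError, match="rank"):
            compute_pca(geno, k=2)

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(5)
        geno = random_genotypes(rng, 40, 80)
        model = compute_pca(geno, k=4)
        for comp in range(4):
            w = model.snp_weights[:, comp]
            assert w[np.argmax(np.abs(w))] > 0


class TestProjection:
    def test_training_samples_reproduce_scores(self, two_pop_cohort):
        (geno, _, _, _), _ = two_pop_cohort
        model = compute_pca(geno, k=5)
        proj = project_samples(model, geno)
        np.testing.assert_allclose(proj, model.sample_scores, atol=1e-8)

    def test_fully_missing_sample_projects_to_origin(self, two_pop_cohort):
        (geno, _, _, _), _ = two_pop_cohort
        model = compute_pca(geno, k=3)
        blank = GenotypeMatrix(
            np.full((1, geno.n_snps), MISSING, dtype=np.int8), ["blank"], geno.snp_ids
        )
        np.testing.assert_allclose(project_samples(model, blank), 0.0)

    def test_source_population_projects_off_center(self, two_pop_cohort):
        """Held-out samples drawn from the divergent source land on the same
        side of the separating axis as the divergent training subpop, with a
        strongly nonzero mean."""
        (geno, _, _, truth), config = two_pop_cohort
        model = compute_pca(geno, k=3)
        rng = np.random.default_rng(6)
        new = rng.binomial(2, truth.subpop_freqs[1], size=(40, config.n_snps)).astype(np.int8)
        new_geno = GenotypeMatrix(new, [f"new{i}" for i in range(40)], geno.snp_ids)
        proj = project_samples(model, new_geno)
        t, p = mean_nonzero_test(proj[:, 0])
        assert p < 1e-10
        train_side = np.sign(model.sample_scores[60:, 0].mean())
        assert np.sign(proj[:, 0].mean()) == train_side

    def test_misaligned_snp_sets_rejected(self, two_pop_cohort):
        (geno, _, _, _), _ = two_pop_cohort
        model = compute_pca(geno, k=2)
        other = GenotypeMatrix(
            np.zeros((1, 3), dtype=np.int8), ["x"], ["a", "b", "c"]
        )
        with pytest.raises(ValueError, match="aligned"):
            project_samples(model, other)


class TestMeanNonzeroTest:
    def test_null_p_uniform(self):
        rng = np.random.default_rng(7)
        ps = [mean_nonzero_test(rng.normal(size=30))[1] for _ in range(200)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_constant_nonzero_scores_floor_p(self):
        t, p = mean_nonzero_test(np.full(10, 3.0))
        assert np.isinf(t) and p == np.finfo(float).tiny

    def test_single_observation_rejected(self):
        with pytest.raises(ValueError):
            mean_nonzero_test(np.array([1.0]))


class TestAncestryCutoff:
    def test_cutoff_outside_hull_removes_none(self, two_pop_cohort):
        (geno, _, _, _), _ = two_pop_cohort
        model = compute_pca(geno, k=2)
        lo = model.sample_scores[:, 0].min()
        cutoff = AncestryCutoff((-1.0, 0.0), lo - 100.0)
        assert ancestry_cutoff_filter(model, cutoff) == []

    def test_boundary_sample_kept(self):
        model = structure.PCAModel(
            eigenvalues=np.array([1.0, 0.5]),
            sample_scores=np.array([[0.0, 0.0], [1.0, 0.0]]),
            snp_weights=np.zeros((2, 2)),
            mu=np.zeros(2), scale=np.ones(2),
            snp_ids=["s", "t"], sample_ids=["on_line", "beyond"],
        )
        cutoff = AncestryCutoff((1.0, 0.0), 0.0)  # boundary at PC1 = 0
        assert ancestry_cutoff_filter(model, cutoff) == ["beyond"]

    def test_planted_admixed_fall_beyond_4sd_cutoff(self):
        """Fully admixed samples from a divergent source separate past a
        cutoff at 4 SD of the main cluster along the separating axis."""
        config = simdata.SimConfig(
            n_subpops=2, samples_per_subpop=80, n_snps=4000,
            subpop_F=[0.001, 0.001], admix_source_F=0.05,
            subpop_latitude=[55, 65], subpop_longitude=[13, 19], seed=8,
        )
        geno, _, _, truth = simdata.simulate_structured_genotypes(config)
        geno = simdata.inject_admixed_samples(geno, truth, 0.1, 1.0, seed=9)
        model = compute_pca(geno, k=2)
        planted = set(truth.admixed_sample_ids)
        main = np.array([s not in planted for s in model.sample_ids])
        pc = model.sample_scores[:, 0]
        # orient the axis toward the admixed side
        direction = 1.0 if pc[~main].mean() > pc[main].mean() else -1.0
        mu, sd = pc[main].mean(), pc[main].std(ddof=1)
        cutoff = AncestryCutoff((direction, 0.0), -(direction * mu + 4 * sd))
        removed = set(ancestry_cutoff_filter(model, cutoff))
        assert len(removed & planted) >= 0.9 * len(planted)
        assert len(removed - planted) <= 0.02 * main.sum()

    def test_zero_normal_rejected(self):
        with pytest.raises(ValueError):
            AncestryCutoff((0.0, 0.0), 1.0)


class TestNearestNeighborOutliers:
    def test_null_gaussian_cloud_removes_almost_none(self):
        # high dimension emulates genotype space, where k-NN distances are
        # near-Gaussian and the 4-SD z-cut has expectation n*k*P(Z>4) << 1
        rng = np.random.default_rng(10)
        coords = rng.normal(size=(500, 50))
        ids = [f"i{i}" for i in range(500)]
        removed = nearest_neighbor_outliers(coords, ids)
        assert len(removed) <= 1

    def test_single_far_outlier_removed_at_k1(self):
        rng = np.random.default_rng(11)
        coords = rng.normal(size=(100, 3))
        radius = np.linalg.norm(coords, axis=1).max()
        coords[0] = 10 * radius
        removed = nearest_neighbor_outliers(coords, [f"i{i}" for i in range(100)])
        assert "i0" in removed

    def test_duplicate_outlier_pair_needs_k_at_least_2(self):
        """Two far-away samples adjacent to each other evade the 1st-NN
        criterion but are caught by the 2nd-NN sweep."""
        rng = np.random.default_rng(12)
        coords = rng.normal(size=(200, 3))
        radius = np.linalg.norm(coords, axis=1).max()
        coords[0] = 10 * radius
        coords[1] = coords[0] + 1e-6
        ids = [f"i{i}" for i in range(200)]
        removed_k1 = nearest_neighbor_outliers(coords, ids, k_max=1)
        removed_k2 = nearest_neighbor_outliers(coords, ids, k_max=2)
        assert "i0" not in removed_k1 and "i1" not in removed_k1
        assert {"i0", "i1"} <= set(removed_k2)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            nearest_neighbor_outliers(np.zeros((4, 2)), list("abcd"), k_max=5)


class TestGeographyRegression:
    @staticmethod
    def _samples(lat, lon):
        return pd.DataFrame(
            {"sample_id": [f"i{i}" for i in range(len(lat))],
             "latitude": lat, "longitude": lon}
        )

    def test_pure_latitude_signal(self):
        rng = np.random.default_rng(13)
        lat = rng.uniform(55, 69, 500)
        lon = rng.uniform(11, 24, 500)
        res = pc_geography_regression(2.0 * lat - 100.0, self._samples(lat, lon))
        assert res["r2_latitude"] == pytest.approx(1.0)
        assert res["delta_r2_longitude_given_latitude"] == pytest.approx(0.0, abs=1e-10)

    def test_null_r2_near_one_over_n(self):
        rng = np.random.default_rng(14)
        n = 2000
        reps = [
            pc_geography_regression(
                rng.normal(size=n),
                self._samples(rng.uniform(55, 69, n), rng.uniform(11, 24, n)),
            )["r2_latitude"]
            for _ in range(20)
        ]
        assert np.mean(reps) == pytest.approx(1 / (n - 1), rel=0.5)

    def test_noisy_gradient_matches_closed_form(self):
        rng = np.random.default_rng(15)
        n = 20_000
        lat = rng.uniform(55, 69, n)
        sigma = 2.0
        signal = 1.5 * lat
        pc = signal + rng.normal(0, sigma, n)
        res = pc_geography_regression(
            pc, self._samples(lat, rng.uniform(11, 24, n))
        )
        expected = signal.var() / (signal.var() + sigma**2)
        assert res["r2_latitude"] == pytest.approx(expected, abs=0.01)


class TestNagelkerke:
    def test_independent_predictor_near_zero(self):
        rng = np.random.default_rng(16)
        y = rng.integers(0, 2, 2000)
        x = rng.normal(size=2000)
        assert nagelkerke_r2(y, x) < 0.02

    def test_noisy_threshold_near_one(self):
        rng = np.random.default_rng(17)
        x = rng.normal(size=2000)
        y = (x > 0).astype(float)
        flip = rng.random(2000) < 0.02
        y[flip] = 1 - y[flip]
        assert nagelkerke_r2(y, x) > 0.85

    def test_empty_predictor_set_is_zero(self):
        rng = np.random.default_rng(18)
        y = rng.integers(0, 2, 100)
        assert nagelkerke_r2(y, np.empty((100, 0))) == 0.0

    def test_perfect_separation_raises(self):
        x = np.linspace(-1, 1, 100)
        y = (x > 0).astype(float)
        with pytest.raises(RuntimeError):
            nagelkerke_r2(y, x)


class TestVarianceShare:
    def test_full_mask_is_one(self):
        s = np.array([1.0, 2.0, 5.0])
        assert variance_share(s, np.ones(3, dtype=bool)) == 1.0

    def test_samples_at_mean_contribute_zero(self):
        s = np.array([0.0, 2.0, 1.0, 1.0])
        assert variance_share(s, np.array([False, False, True, True])) == 0.0

    def test_two_cluster_hand_computation(self):
        # minority of 2 at +3, majority of 6 at 0: mean=0.75
        s = np.array([3.0, 3.0, 0, 0, 0, 0, 0, 0])
        mask = np.array([True, True] + [False] * 6)
        dev = (s - 0.75) ** 2
        assert variance_share(s, mask) == pytest.approx(dev[:2].sum() / dev.sum())


class TestJitter:
    def test_zero_radius_identity(self):
        tab = pd.DataFrame(
            {"sample_id": ["a"], "latitude": [58.0], "longitude": [15.0]}
        )
        out = jitter_coordinates(tab, 0.0, seed=1)
        assert out["latitude"].iloc[0] == 58.0

    def test_reproducible_and_bounded(self):
        rng = np.random.default_rng(19)
        tab = pd.DataFrame(
            {"sample_id": [f"i{i}" for i in range(100)],
             "latitude": rng.uniform(55, 69, 100),
             "longitude": rng.uniform(11, 24, 100)}
        )
        a = jitter_coordinates(tab, 0.1, seed=2)
        b = jitter_coordinates(tab, 0.1, seed=2)
        pd.testing.assert_frame_equal(a, b)
        assert (np.abs(a["latitude"] - tab["latitude"]) <= 0.1).all()


class TestInbreedingPcPathway:
    def test_autozygosity_gradient_detected_in_pc_direction(self):
        """One subpop contains an isolation gradient: samples with more
        source ancestry also carry more autozygosity. The within-subpop
        regression of the separating PC on the ROH-module inbreeding
        coefficient must point the same way as the planted ancestry
        gradient in >= 18 of 20 replicates."""
        correct = 0
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            n_a, n_b, m = 60, 60, 800
            p = rng.uniform(0.1, 0.5, m)
            p_src = np.clip(p + rng.normal(0, 0.15, m), 0.02, 0.98)
            ga = rng.binomial(2, p, size=(n_a, m))
            a_frac = rng.uniform(0, 1, n_b)  # per-sample source ancestry
            gb = np.empty((n_b, m), dtype=np.int64)
            for i in range(n_b):
                pi = (1 - a_frac[i]) * p + a_frac[i] * p_src
                autozygous = rng.random(m) < 0.25 * a_frac[i]
                g = rng.binomial(2, pi)
                g[autozygous] = 2 * rng.binomial(1, pi[autozygous])
                gb[i] = g
            geno = GenotypeMatrix(
                np.vstack([ga, gb]).astype(np.int8),
                [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)],
                [f"s{j}" for j in range(m)],
            )
            model = compute_pca(geno, k=2)
            f = roh.inbreeding_coefficients(geno).to_numpy()[n_a:]
            pc_b = model.sample_scores[n_a:, 0]
            planted = np.corrcoef(pc_b, a_frac)[0, 1]
            detected = np.corrcoef(pc_b, f)[0, 1]
            if np.sign(planted) == np.sign(detected):
                correct += 1
        assert correct >= 18
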