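"""PCA, circular statistics, hierarchical bootstrap, sum rule, tests, fits."""

import numpy as np
import pytest
from scipy import stats as sps

from pawkit import ValidationError
from pawkit.stats import (
    circular_sd_deg,
    fit_pose_pca,
    friedman_dunn,
    hierarchical_bootstrap,
    project_trajectories,
    pulse_matched_latency,
    regression_fits,
    shuffle_parts,
    sum_rule,
    trajectory_direction_stats,
)
from pawkit.synthetic import gen_nested_values


class TestPosePCA:
    def test_collinear_data_pc1_explains_everything(self):
        t = np.linspace(0, 1, 30)
        X = np.outer(t, np.arange(1, 13, dtype=float))
        model = fit_pose_pca(X, k=3)
        assert model.explained_variance[0] == pytest.approx(1.0)

    def test_explained_fractions_match_eigenvalue_ratios(self, rng):
        eig = np.array([4.0, 2.0, 1.0] + [0.1] * 9)
        X = rng.normal(size=(4000, 12)) * np.sqrt(eig)
        model = fit_pose_pca(X, k=3)
        expected = eig[:3] / eig.sum()
        assert np.allclose(model.explained_variance, expected, atol=0.02)

    def test_matches_sklearn_oracle(self, rng):
        sklearn = pytest.importorskip("sklearn.decomposition")
        X = rng.normal(size=(50, 12))
        model = fit_pose_pca(X, k=3)
        sk = sklearn.PCA(n_components=3).fit(X)
        assert np.allclose(model.explained_variance, sk.explained_variance_ratio_)
        for ours, theirs in zip(model.loadings, sk.components_):
            assert np.allclose(ours, theirs) or np.allclose(ours, -theirs)

    def test_sign_convention_and_determinism(self, rng):
        X = rng.normal(size=(40, 12))
        a = fit_pose_pca(X, k=3)
        b = fit_pose_pca(X, k=3)
        assert np.array_equal(a.loadings, b.loadings)
        for row in a.loadings:
            assert row[np.argmax(np.abs(row))] > 0

    def test_train_test_split_report(self, rng):
        X = rng.normal(size=(80, 12)) * np.sqrt(np.arange(12, 0, -1))
        model = fit_pose_pca(X, k=3, split=0.8, split_seed=0)
        assert "train_explained" in model.split_report
        assert "test_explained" in model.split_report
        assert model.split_report["train_explained"].shape == (3,)

    def test_rank_deficient_warns(self, rng):
        X = np.tile(rng.normal(size=(1, 12)), (10, 1))
        X[::2] += rng.normal(size=12)  # rank 2 after centering -> < k
        with pytest.warns(RuntimeWarning, match="rank"):
            fit_pose_pca(X, k=3)


class TestProjectTrajectories:
    def test_projection_consistent_with_fit_scores(self, rng):
        X = rng.normal(size=(30, 12))
        model = fit_pose_pca(X, k=3)
        scores, _ = project_trajectories(X[:, None, :], model)
        manual = (X - model.mean) @ model.loadings.T
        assert np.allclose(np.vstack(scores), manual)

    def test_model_mean_projects_to_zero(self, rng):
        X = rng.normal(size=(30, 12))
        model = fit_pose_pca(X, k=3)
        scores, _ = project_trajectories(model.mean[None, None, :], model)
        assert np.allclose(scores[0], 0.0)

    def test_explained_variance_matches_residual_oracle(self, rng):
        X = rng.normal(size=(5, 40, 12)) * np.sqrt(np.arange(12, 0, -1))
        model = fit_pose_pca(X[:, 20, :], k=3)
        _, per_pc = project_trajectories(X, model)
        P = X.reshape(-1, 12)
        Pc = P - P.mean(axis=0)
        recon = (Pc @ model.loadings.T) @ model.loadings
        explained = 1.0 - ((Pc - recon) ** 2).sum() / (Pc**2).sum()
        assert per_pc.sum() == pytest.approx(explained, abs=1e-9)

    def test_nan_frames_skipped(self, rng):
        X = rng.normal(size=(2, 10, 12))
        X[0, 3, 5] = np.nan
        model = fit_pose_pca(X[:, 0, :].repeat(3, axis=0), k=2)
        scores, _ = project_trajectories(X, model)
        assert np.isnan(scores[0][3]).all() and np.isfinite(scores[0][4]).all()


class TestDirectionStats:
    def test_common_direction_zero_sd(self):
        trajs = [np.outer(np.linspace(0, i + 1, 50), [1.0, 0.0]) for i in range(5)]
        times = np.linspace(-25, 220, 50)
        _, csd, n = trajectory_direction_stats(trajs, times)
        assert csd == pytest.approx(0.0, abs=1e-9) and n == 5

    def test_two_perpendicular_trials_closed_form(self):
        """R = sqrt(2)/2 gives circular SD sqrt(-2 ln R) = 47.70 deg."""
        t = np.linspace(0, 1, 50)
        trajs = [np.outer(t, [1.0, 0.0]), np.outer(t, [0.0, 1.0])]
        times = np.linspace(-25, 220, 50)
        _, csd, _ = trajectory_direction_stats(trajs, times)
        assert csd == pytest.approx(np.degrees(np.sqrt(np.log(2))), abs=1e-9)
        assert csd == pytest.approx(47.70, abs=0.01)

    def test_von_mises_matches_analytic_dispersion(self, rng):
        kappa = 4.0
        angles = rng.vonmises(0.0, kappa, size=4000)
        t = np.linspace(0, 1, 50)
        trajs = [np.outer(t, [np.cos(a), np.sin(a)]) for a in angles]
        times = np.linspace(-25, 220, 50)
        _, csd, _ = trajectory_direction_stats(trajs, times)
        expected = np.degrees(np.sqrt(-2 * np.log(sps.vonmises.expect(
            lambda x: np.cos(x), args=(kappa,)))))
        assert csd == pytest.approx(expected, rel=0.05)

    def test_rotation_invariance(self, rng):
        angles = rng.uniform(0, 2 * np.pi, size=100)
        t = np.linspace(0, 1, 50)
        times = np.linspace(-25, 220, 50)
        trajs = [np.outer(t, [np.cos(a), np.sin(a)]) for a in angles]
        rot = [np.outer(t, [np.cos(a + 0.7), np.sin(a + 0.7)]) for a in angles]
        _, sd1, _ = trajectory_direction_stats(trajs, times)
        _, sd2, _ = trajectory_direction_stats(rot, times)
        assert sd1 == pytest.approx(sd2, abs=1e-9)

    def test_part_shuffle_increases_dispersion(self, rng):
        # coherent trials: part j always moves along its own direction, so
        # trials share a trajectory direction until part identity is shuffled
        t = np.linspace(-25, 220, 50)
        ramp = np.clip(t, 0, None)
        dirs = np.concatenate([[np.cos(np.radians(60 * j)), np.sin(np.radians(60 * j))]
                               for j in range(6)])
        feats = np.stack([
            np.outer(ramp, dirs) * (1 + 0.1 * rng.normal())
            + rng.normal(0, 0.5, size=(50, 12))
            for _ in range(40)
        ])
        model = fit_pose_pca(feats[:, -1, :], k=3)
        trajs, _ = project_trajectories(feats, model)
        _, sd_real, _ = trajectory_direction_stats(trajs, t)
        _, sd_shuf, _ = trajectory_direction_stats(
            trajs, t, shuffle="parts", seed=0, model=model, features=feats)
        assert sd_shuf > sd_real

    def test_shuffle_parts_permutes_xy_pairs(self, rng):
        F = rng.normal(size=(3, 4, 12))
        out = shuffle_parts(F, np.random.default_rng(0))
        for i in range(3):
            orig = {tuple(np.round(F[i, 0].reshape(6, 2)[j], 9)) for j in range(6)}
            perm = {tuple(np.round(out[i, 0].reshape(6, 2)[j], 9)) for j in range(6)}
            assert orig == perm


class TestHierarchicalBootstrap:
    def test_constant_values_zero_se(self):
        est = hierarchical_bootstrap({"a": [5.0, 5.0], "b": [5.0]},
                                     n_boot=200, seed=0)
        assert est.estimate == 5.0 and est.se == 0.0

    def test_single_mouse_matches_one_level_bootstrap(self):
        """With one mouse the scheme reduces to an ordinary bootstrap."""
        values = np.array([1.0, 2.0, 3.0])
        est = hierarchical_bootstrap({"m": values}, estimator="mean",
                                     n_boot=20000, k=3, seed=1)
        rng = np.random.default_rng(2)
        naive = rng.choice(values, size=(20000, 3), replace=True).mean(axis=1)
        assert est.estimate == pytest.approx(naive.mean(), abs=0.02)
        assert est.se == pytest.approx(naive.std(), abs=0.02)

    def test_balanced_default_k_is_mean_trials(self):
        # 2 + 4 trials -> k = 3; resample statistic sees 2 mice x 3 trials
        est = hierarchical_bootstrap({"a": [1.0, 1.0], "b": [2.0, 2.0, 2.0, 2.0]},
                                     estimator="mean", n_boot=2000, seed=3)
        # equal contribution: estimate near the mouse-mean average 1.5
        assert est.estimate == pytest.approx(1.5, abs=0.05)

    def test_truth_covered_within_two_se(self):
        hits = 0
        for rep in range(40):
            vals = gen_nested_values(8, 8, 30.0, 2.0, 5.0, seed=500 + rep)
            est = hierarchical_bootstrap(vals, estimator="median",
                                         n_boot=1000, seed=rep)
            hits += abs(est.estimate - 30.0) <= 2 * est.se
        assert hits >= 36  # >= 90% at this scale; acceptance runs 100 reps

    def test_reproducible_under_seed(self):
        vals = gen_nested_values(seed=9)
        a = hierarchical_bootstrap(vals, n_boot=500, seed=42)
        b = hierarchical_bootstrap(vals, n_boot=500, seed=42)
        assert a.estimate == b.estimate and a.se == b.se


class TestSumRule:
    def test_published_five_pulse_probability(self):
        assert sum_rule(0.096, 5) == pytest.approx(0.3963, abs=5e-5)
        assert round(sum_rule(0.096, 5), 2) == 0.40

    @pytest.mark.parametrize("p,n,expected", [(0.0, 7, 0.0), (1.0, 3, 1.0),
                                              (0.25, 1, 0.25)])
    def test_boundary_identities(self, p, n, expected):
        assert sum_rule(p, n) == pytest.approx(expected)

    def test_monotone_in_p_and_n(self):
        ps = np.linspace(0.01, 0.99, 25)
        vals = [sum_rule(p, 4) for p in ps]
        assert all(a < b for a, b in zip(vals, vals[1:]))
        vals_n = [sum_rule(0.2, n) for n in range(1, 10)]
        assert all(a < b for a, b in zip(vals_n, vals_n[1:]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            sum_rule(1.2, 3)


class TestPulseMatchedLatency:
    @pytest.mark.parametrize("lat,isi,n,idx,resid", [
        (250.0, 100.0, 5, 2, 50.0),
        (50.0, 200.0, 5, 0, 50.0),
        (950.0, 100.0, 5, 4, 550.0),  # capped at the last pulse
    ])
    def test_index_and_residual(self, lat, isi, n, idx, resid):
        i, r, ratio = pulse_matched_latency(lat, isi, n)
        assert i == idx and r == pytest.approx(resid)
        assert ratio == pytest.approx(lat / isi)


class TestFriedmanDunn:
    def test_identical_columns_no_effect(self):
        res = friedman_dunn(np.ones((4, 3)))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_strict_ordering_hand_computed(self):
        res = friedman_dunn(np.array([[1, 2, 3], [2, 4, 6], [1, 5, 9]], float))
        assert res.statistic == pytest.approx(6.0)
        assert res.df == 2

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(10):
            X = rng.normal(size=(8, 4))
            ours = friedman_dunn(X)
            ref = sps.friedmanchisquare(*(X[:, j] for j in range(4)))
            assert ours.statistic == pytest.approx(ref.statistic)
            assert ours.p_value == pytest.approx(ref.pvalue)

    def test_missing_cells_rejected(self):
        X = np.ones((3, 3))
        X[1, 2] = np.nan
        with pytest.raises(ValidationError):
            friedman_dunn(X)

    def test_dunn_pairwise_present(self, rng):
        res = friedman_dunn(rng.normal(size=(6, 3)), adjust="bonferroni")
        assert len(res.pairwise) == 3
        assert all("p_adj" in d for d in res.pairwise)


class TestRegressionFits:
    def test_exact_line(self):
        x = np.arange(1, 11, dtype=float)
        res = regression_fits(x, 2 * x + 1, "linear")
        assert res.coefficients["slope"] == pytest.approx(2.0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.pearson_r == pytest.approx(1.0)

    def test_power_law_recovered_in_loglog(self):
        x = np.linspace(0.5, 9, 20)
        y = 3.0 * x**1.7
        res = regression_fits(x, y, "loglog")
        assert res.coefficients["slope"] == pytest.approx(1.7)
        assert 10 ** res.coefficients["log10_intercept"] == pytest.approx(3.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_lognormal_y_on_logx(self):
        x = np.array([1.0, 10.0, 100.0, 1000.0])
        y = np.array([2.0, 4.0, 6.0, 8.0])  # linear in log10 x
        res = regression_fits(x, y, "lognormal")
        assert res.coefficients["slope"] == pytest.approx(2.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_noisy_fit_matches_normal_equations(self, rng):
        x = rng.uniform(1, 10, 40)
        y = 2.5 * x**0.8 * np.exp(rng.normal(0, 0.1, 40))
        res = regression_fits(x, y, "loglog")
        A = np.column_stack([np.log10(x), np.ones_like(x)])
        beta = np.linalg.lstsq(A, np.log10(y), rcond=None)[0]
        assert res.coefficients["slope"] == pytest.approx(beta[0])
        assert res.coefficients["log10_intercept"] == pytest.approx(beta[1])

    def test_nonpositive_values_rejected_with_indices(self):
        with pytest.raises(ValidationError, match="indices"):
            regression_fits(np.array([1.0, -2.0, 3.0, 4.0]),
                            np.array([1.0, 2.0, 3.0, 4.0]), "loglog")


class TestCircularSD:
    def test_uniform_directions_large_sd(self, rng):
        sd = circular_sd_deg(rng.uniform(-180, 180, 20000))
        assert sd > 120.0  # R -> 0, sd -> inf; far above any coherent set
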