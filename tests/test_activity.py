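"""DiMA differential-activity test, explained variance, trendlines."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import imodkit as ik
from imodkit.activity import (DimaNull, dima, distance_to_trendline,
                              explained_variance, fit_dima_null,
                              fit_trendline, rank_by_explained_variance)
from imodkit.synthetic import generate_paired_activities


class TestDimaNull:
    def test_lognormal_mle_recovered(self):
        # |d| ~ LogNormal(0, 1): the MLE is mean/SD of logs, recomputed here
        rng = np.random.default_rng(0)
        n_pairs = 500
        d = rng.lognormal(0.0, 1.0, size=(1, n_pairs))
        A = pd.DataFrame(
            np.column_stack([np.zeros((1, n_pairs)), d]).reshape(1, -1)
        )
        # interleave pairs (sample 2i, 2i+1) = (0, d_i)
        vals = np.empty((1, 2 * n_pairs))
        vals[0, ::2] = 0.0
        vals[0, 1::2] = d[0]
        A = pd.DataFrame(vals, index=["im1"],
                         columns=[f"s{i}" for i in range(2 * n_pairs)])
        design = ik.default_design(n_pairs, 2)
        A.columns = design.samples
        null = fit_dima_null(A, design)
        assert null.n_pairs == n_pairs
        assert abs(null.params.loc["im1", "mu"]) < 3 * 1.0 / np.sqrt(n_pairs) + 0.01
        assert abs(null.params.loc["im1", "sigma"] - 1.0) < 0.15

    def test_identical_replicates_degenerate(self):
        design = ik.default_design(2, 2)
        A = pd.DataFrame(np.ones((2, 4)), index=["a", "b"],
                         columns=design.samples)
        with pytest.raises(ValueError, match="degenerate"):
            fit_dima_null(A, design)

    def test_epsilon_floor_recorded(self):
        A, design = generate_paired_activities(2, 5, seed=1)
        null = fit_dima_null(A, design)
        assert null.epsilon == 1e-6

    def test_too_few_pairs_rejected(self):
        design = ik.default_design(1, 2)
        A = pd.DataFrame(np.random.default_rng(2).normal(size=(2, 2)),
                         index=["a", "b"], columns=design.samples)
        with pytest.raises(ValueError, match="pairs"):
            fit_dima_null(A, design)


class TestDima:
    def _null(self, imods, mu=0.0, sigma=1.0):
        params = pd.DataFrame({"mu": mu, "sigma": sigma}, index=imods)
        return DimaNull(params=params, n_pairs=10)

    def test_identical_groups_not_significant(self):
        A = pd.DataFrame(
            np.tile(np.arange(3.0)[:, None], 8),
            index=["a", "b", "c"], columns=[f"s{i}" for i in range(8)],
        )
        res = dima(A, [f"s{i}" for i in range(4)],
                   [f"s{i}" for i in range(4, 8)], self._null(["a", "b", "c"]))
        assert (res["pvalue"] == 1.0).all() or (res["pvalue"] > 0.999).all()
        assert not res["significant"].any()

    def test_observed_difference_at_null_median_gives_half(self):
        mu = 1.2
        A = pd.DataFrame(
            [[0.0, 0.0, np.exp(mu), np.exp(mu)]], index=["a"],
            columns=["s0", "s1", "s2", "s3"],
        )
        res = dima(A, ["s0", "s1"], ["s2", "s3"], self._null(["a"], mu=mu))
        assert res["pvalue"].iloc[0] == pytest.approx(0.5, abs=1e-4)

    def test_single_planted_shift_is_the_only_hit(self):
        # null with median e^0 = 1 and tight spread; shift of 10 on one
        # component gives survival ~ norm.sf(ln 10 / 0.3) < 1e-4
        k = 6
        imods = [f"im{i}" for i in range(k)]
        null = self._null(imods, mu=0.0, sigma=0.3)
        vals = np.zeros((k, 8))
        vals[2, 4:] = 10.0
        A = pd.DataFrame(vals, index=imods, columns=[f"s{i}" for i in range(8)])
        res = dima(A, [f"s{i}" for i in range(4)],
                   [f"s{i}" for i in range(4, 8)], null)
        assert res.loc[res["imodulon"] == "im2", "significant"].iloc[0]
        assert res["significant"].sum() == 1
        expect_p = norm.sf(np.log(10.0) / 0.3)
        assert res.loc[res["imodulon"] == "im2", "pvalue"].iloc[0] == \
            pytest.approx(expect_p, rel=1e-3)

    def test_default_thresholds(self):
        import inspect
        sig = inspect.signature(dima)
        assert sig.parameters["diff_threshold"].default == 5.0
        assert sig.parameters["fdr_threshold"].default == 0.1

    def test_unknown_samples_rejected(self):
        A = pd.DataFrame(np.zeros((1, 2)), index=["a"], columns=["s0", "s1"])
        with pytest.raises(ValueError, match="unknown"):
            dima(A, ["s0"], ["nope"], self._null(["a"]))

    def test_overlapping_groups_rejected(self):
        A = pd.DataFrame(np.zeros((1, 3)), index=["a"],
                         columns=["s0", "s1", "s2"])
        with pytest.raises(ValueError, match="disjoint"):
            dima(A, ["s0", "s1"], ["s1", "s2"], self._null(["a"]))


def _orthogonal_decomposition(seed=0):
    """3 mutually orthogonal components of equal Frobenius power."""
    G, S = 60, 12
    M = np.zeros((G, 3))
    M[0:10, 0] = 1; M[10:20, 1] = 1; M[20:30, 2] = 1
    M /= np.linalg.norm(M, axis=0)
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(3, S))
    # orthogonalize rows and set equal power
    q, _ = np.linalg.qr(A.T)
    A = q.T[:3] * 5.0
    X = M @ A
    return X, pd.DataFrame(M, columns=["c1", "c2", "c3"]), \
        pd.DataFrame(A, index=["c1", "c2", "c3"])


class TestExplainedVariance:
    def test_exact_reconstruction_gives_one(self):
        X, M, A = _orthogonal_decomposition()
        assert explained_variance(X, M, A) == pytest.approx(1.0, abs=1e-12)

    def test_empty_subset_gives_zero(self):
        X, M, A = _orthogonal_decomposition()
        assert explained_variance(X, M, A, imodulon_subset=[]) == 0.0

    def test_orthogonal_components_split_evenly(self):
        X, M, A = _orthogonal_decomposition()
        for c in M.columns:
            ev = explained_variance(X, M, A, imodulon_subset=[c])
            assert ev == pytest.approx(1 / 3, abs=1e-9)

    def test_sign_flip_invariance(self):
        X, M, A = _orthogonal_decomposition()
        M2, A2 = M.copy(), A.copy()
        M2["c2"] *= -1
        A2.loc["c2"] *= -1
        assert explained_variance(X, M2, A2) == pytest.approx(
            explained_variance(X, M, A), abs=1e-12
        )

    def test_zero_matrix_rejected(self):
        _, M, A = _orthogonal_decomposition()
        with pytest.raises(ValueError, match="undefined"):
            explained_variance(np.zeros((60, 12)), M, A)


class TestRankByExplainedVariance:
    def test_orthogonal_cumulative_reaches_one(self):
        X, M, A = _orthogonal_decomposition()
        table = rank_by_explained_variance(X, M, A)
        assert table["cumulative_ev"].iloc[-1] == pytest.approx(1.0, abs=1e-9)

    def test_cumulative_nondecreasing_and_bounded(self):
        rng = np.random.default_rng(1)
        for rep in range(20):
            G, k, S = 40, 4, 10
            M = rng.normal(size=(G, k))
            M /= np.linalg.norm(M, axis=0)
            A = rng.normal(size=(k, S)) * 3
            X = M @ A + rng.normal(0, 0.2, size=(G, S))
            table = rank_by_explained_variance(
                X, pd.DataFrame(M, columns=[f"c{i}" for i in range(k)]),
                pd.DataFrame(A, index=[f"c{i}" for i in range(k)]),
            )
            cum = table["cumulative_ev"].to_numpy()
            assert np.all(np.diff(cum) >= -1e-9)
            assert cum[-1] <= 1 + 1e-9

    def test_duplicate_component_adds_nothing(self):
        # cumulative reconstruction projects onto the prefix span, so a
        # duplicated column changes nothing
        X, M, A = _orthogonal_decomposition()
        full = explained_variance(X, M, A, imodulon_subset=["c1", "c2", "c3"])
        dup = explained_variance(
            pd.DataFrame(X), M[["c1", "c2", "c3", "c1"]].set_axis(
                ["c1", "c2", "c3", "d"], axis=1),
            pd.concat([A, A.loc[["c1"]].set_axis(["d"])]),
            imodulon_subset=["c1", "c2", "c3", "d"], refit_A=True,
        )
        assert dup == pytest.approx(full, abs=1e-9)


class TestTrendlines:
    def test_exact_line(self):
        x = np.arange(10.0)
        fit = fit_trendline(x, 2 * x, model="linear")
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.residual_scale < 1e-12

    def test_logarithmic_coefficients(self):
        x = np.arange(1.0, 51.0)
        y = 3 * np.log(x) + 1
        fit = fit_trendline(x, y, model="logarithmic")
        # x_min = 1 makes the shifted abscissa ln(x) exactly
        assert fit.slope == pytest.approx(3.0, abs=1e-6)
        assert fit.intercept == pytest.approx(1.0, abs=1e-6)

    def test_under_minimum_points_rejected(self):
        with pytest.raises(ValueError, match="3"):
            fit_trendline([0, 1], [0, 1], model="linear")

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_trendline([2, 2, 2], [1, 2, 3], model="linear")

    def test_distance_signs_and_leastsq_identity(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 10, 40)
        y = 1.5 * x + rng.normal(0, 2, 40)
        fit = fit_trendline(x, y, model="linear")
        d = distance_to_trendline(x, y, fit)
        assert abs(d.mean()) < 1e-9  # normal-equations identity
        x0 = np.array([3.0])
        y_on = fit.predict(x0)
        assert distance_to_trendline(x0, y_on, fit)[0] == pytest.approx(0.0)
        assert distance_to_trendline(x0, y_on + 2, fit)[0] == pytest.approx(2.0)

    def test_fit_mask_excludes_deviating_points(self):
        x = np.arange(20.0)
        y = 2 * x
        y[-3:] += 50  # deviating samples
        mask = np.ones(20, bool)
        mask[-3:] = False
        fit = fit_trendline(x, y, model="linear", fit_mask=mask)
        assert fit.slope == pytest.approx(2.0, abs=1e-9)
        d = distance_to_trendline(x, y, fit)
        assert np.all(d[-3:] > 49)
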