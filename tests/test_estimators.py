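import numpy as np
import pytest
from scipy import stats

from mrgrip import (
    ConfigError,
    InstabilityError,
    SummaryDataset,
    ValidationError,
    cochran_q,
    estimates_to_frame,
    estimates_to_json,
    intercept_test,
    ivw,
    mean_f_statistic,
    mode_based,
    mr_egger,
    mr_grip,
    mr_grip_weak,
    ratio_estimates,
    weighted_median,
)
from mrgrip.estimators import _mode_point, _weighted_median_point


def wls_oracle(X, y, w):
    """Independent normal-equation solution of the weighted LS problem."""
    X = np.atleast_2d(X)
    A = X.T @ (w[:, None] * X)
    b = X.T @ (w * y)
    return np.linalg.solve(A, b)


def simple_ds(beta_exp, beta_out, se_out, se_exp=None):
    m = len(beta_exp)
    return SummaryDataset(
        snp_id=np.array([f"s{i}" for i in range(m)], dtype=object),
        beta_exp=beta_exp,
        se_exp=np.full(m, 0.01) if se_exp is None else se_exp,
        beta_out=beta_out,
        se_out=se_out,
    )


class TestRatioEstimates:
    def test_definitional(self):
        ds = simple_ds([2.0, 0.1], [1.0, 0.03], [1.0, 0.02])
        r = ratio_estimates(ds)
        np.testing.assert_allclose(r.ratio, [0.5, 0.3])
        np.testing.assert_allclose(r.weight, [4.0, 25.0])

    def test_zero_exposure_names_snp(self):
        ds = simple_ds([2.0, 0.0], [1.0, 0.03], [1.0, 0.02])
        with pytest.raises(ValidationError, match="s1"):
            ratio_estimates(ds)


class TestIVW:
    def test_matches_normal_equation_oracle(self):
        g = np.array([0.1, -0.2, 0.3])
        G = np.array([0.03, -0.02, 0.08])
        sy = np.array([0.05, 0.04, 0.06])
        est = ivw(simple_ds(g, G, sy))
        expected = wls_oracle(g[:, None], G, sy**-2.0)[0]
        assert est.beta == pytest.approx(expected, abs=1e-12)
        # closed form
        assert est.beta == pytest.approx(
            np.sum(sy**-2 * G * g) / np.sum(sy**-2 * g**2), abs=1e-14
        )

    def test_single_snp(self):
        est = ivw(simple_ds([0.2], [0.05], [0.1]))
        assert est.beta == pytest.approx(0.25)
        assert est.se_beta == pytest.approx(0.1 / 0.2)

    def test_ci_brackets_and_normal_p(self, make_random_dataset, rng):
        est = ivw(make_random_dataset(rng))
        assert est.ci_low < est.beta < est.ci_high
        z = abs(est.beta) / est.se_beta
        assert est.p_beta == pytest.approx(2 * stats.norm.sf(z))


class TestMREgger:
    def test_exact_line_recovered(self):
        g = np.array([0.1, 0.2, 0.3, 0.4])
        est = mr_egger(simple_ds(g, 0.3 + 0.5 * g, np.full(4, 0.05)))
        assert est.intercept == pytest.approx(0.3, abs=1e-10)
        assert est.beta == pytest.approx(0.5, abs=1e-10)
        assert est.residual_scale == pytest.approx(0.0, abs=1e-6)

    def test_matches_wls_oracle_under_both_codings(self, make_random_dataset, rng):
        ds = make_random_dataset(rng, m=12)
        for coding in ("as-given", "all-positive"):
            est = mr_egger(ds, coding=coding)
            g = np.abs(ds.beta_exp) if coding == "all-positive" else ds.beta_exp
            G = np.sign(ds.beta_exp) * ds.beta_out if coding == "all-positive" else ds.beta_out
            X = np.column_stack([np.ones(ds.m), g])
            expected = wls_oracle(X, G, ds.se_out**-2.0)
            assert est.intercept == pytest.approx(expected[0], abs=1e-12)
            assert est.beta == pytest.approx(expected[1], abs=1e-12)

    def test_preconditions(self, toy_ds):
        with pytest.raises(ValidationError):
            mr_egger(toy_ds.select(np.array([0, 1])))
        with pytest.raises(ConfigError):
            mr_egger(toy_ds, coding="sideways")

    def test_collinear_design_rejected(self):
        # constant exposure effects leave the slope indistinguishable from
        # the intercept
        ds = simple_ds(np.full(5, 0.2), np.linspace(0, 0.1, 5), np.full(5, 0.05))
        with pytest.raises(InstabilityError):
            mr_egger(ds, coding="as-given")


class TestMRGrip:
    def test_matches_two_parameter_wls_oracle(self):
        g = np.array([0.1, -0.2, 0.3, 0.15])
        G = np.array([0.03, -0.06, 0.05, 0.02])
        sy = np.array([0.05, 0.04, 0.06, 0.05])
        est = mr_grip(simple_ds(g, G, sy))
        X = np.column_stack([np.ones(4), g**2])
        expected = wls_oracle(X, G * g, g**-2.0 * sy**-2.0)
        assert est.intercept == pytest.approx(expected[0], abs=1e-12)
        assert est.beta == pytest.approx(expected[1], abs=1e-12)

    def test_zero_intercept_equals_ivw(self, make_random_dataset, rng):
        for _ in range(5):
            ds = make_random_dataset(rng)
            assert mr_grip(ds, fix_intercept_zero=True).beta == pytest.approx(
                ivw(ds).beta, abs=1e-12
            )

    def test_preconditions(self, toy_ds):
        with pytest.raises(ValidationError):
            mr_grip(toy_ds.select(np.array([0, 1])))
        bad = simple_ds([0.1, 0.0, 0.2], [0.1, 0.1, 0.1], [0.1, 0.1, 0.1])
        with pytest.raises(ValidationError, match="s1"):
            mr_grip(bad)

    def test_constant_grip_regressor_rejected(self):
        # equal gamma-squared makes the GRIP regressor constant
        ds = simple_ds(np.array([0.2, -0.2, 0.2, -0.2]),
                       np.array([0.05, -0.04, 0.06, -0.05]), np.full(4, 0.05))
        with pytest.raises(InstabilityError):
            mr_grip(ds)


class TestMRGripWeak:
    def test_nome_limit_equals_sigma_y_weighted_grip(self, make_random_dataset, rng):
        ds = make_random_dataset(rng, m=15)
        ds = SummaryDataset(ds.snp_id, ds.beta_exp, np.full(ds.m, 1e-12),
                            ds.beta_out, ds.se_out)
        est = mr_grip_weak(ds)
        # with negligible exposure-side error the corrections vanish and the
        # estimate is the two-parameter regression of Gamma*gamma on gamma^2
        # with plain inverse-variance weights
        g, G, w = ds.beta_exp, ds.beta_out, ds.se_out**-2.0
        X = np.column_stack([np.ones(ds.m), g**2])
        expected = wls_oracle(X, G * g, w)
        assert est.beta == pytest.approx(expected[1], rel=1e-9)
        assert est.intercept == pytest.approx(expected[0], rel=1e-6)

    def test_moment_corrections_unbiased(self, rng):
        # gamma-hat ~ N(gamma, sigma^2): the plug-in products average to the
        # true odd/even moments of gamma
        gamma, sigma = 0.17, 0.23
        n = 2_000_000
        gh = rng.normal(gamma, sigma, size=n)
        for expr, truth in [
            (gh * (gh**2 - 3 * sigma**2), gamma**3),
            (gh**2 - sigma**2, gamma**2),
            (gh**4 - 6 * gh**2 * sigma**2 + 3 * sigma**4, gamma**4),
        ]:
            mc_se = expr.std(ddof=1) / np.sqrt(n)
            assert abs(expr.mean() - truth) < 4 * mc_se

    def test_degenerate_denominator_raises(self):
        # every gamma-hat sits where the corrected fourth moment
        # g^4 - 6 g^2 s^2 + 3 s^4 is negative, driving the denominator below 0
        ds = simple_ds(np.array([0.10, -0.12, 0.14, 0.11]),
                       np.array([0.01, 0.0, 0.02, 0.01]),
                       np.full(4, 0.05), se_exp=np.full(4, 0.1))
        with pytest.raises(InstabilityError):
            mr_grip_weak(ds)

    def test_jackknife_se_positive(self, make_random_dataset, rng):
        est = mr_grip_weak(make_random_dataset(rng))
        assert est.se_beta > 0 and est.se_intercept > 0


class TestWeightedMedian:
    def test_hand_interpolated_median(self):
        # ratios 1..5, weights (5,1,1,1,2): centred cumulative fractions are
        # (0.25, 0.55, 0.65, 0.75, 0.9); 0.5 interpolates between the first
        # two ordered ratios at 1 + 0.25/0.30
        assert _weighted_median_point(
            np.array([1.0, 2, 3, 4, 5]), np.array([5.0, 1, 1, 1, 2])
        ) == pytest.approx(1.0 + 0.25 / 0.30, abs=1e-12)

    def test_equal_weights_odd_count_is_middle(self):
        assert _weighted_median_point(np.array([5.0, 1, 3, 2, 4]),
                                      np.ones(5)) == pytest.approx(3.0)

    def test_constant_ratios(self):
        ds = simple_ds(np.array([0.1, 0.2, 0.4]), 0.3 * np.array([0.1, 0.2, 0.4]),
                       np.full(3, 0.02))
        est = weighted_median(ds, n_boot=200, seed=7)
        assert est.beta == pytest.approx(0.3)
        assert est.se_beta < 0.05

    def test_config_errors(self, toy_ds):
        with pytest.raises(ConfigError):
            weighted_median(toy_ds, n_boot=1, seed=1)


class TestModeBased:
    def test_constant_ratios(self):
        ds = simple_ds(np.array([0.1, 0.2, 0.4]), 0.3 * np.array([0.1, 0.2, 0.4]),
                       np.full(3, 0.02))
        est = mode_based(ds, n_boot=50, seed=3)
        assert est.beta == pytest.approx(0.3, abs=1e-6)

    def test_bimodal_majority_cluster_wins(self):
        ratios = np.array([0.2] * 7 + [0.8] * 3) + np.linspace(-0.005, 0.005, 10)
        mode = _mode_point(ratios, np.ones(10))
        assert abs(mode - 0.2) < 0.05
        # independent dense grid-search oracle over the same kernel density
        sd = np.std(ratios, ddof=1)
        mad = stats.median_abs_deviation(ratios, scale="normal")
        h = 0.9 * min(sd, mad) * 10 ** (-0.2)
        grid = np.linspace(-0.5, 1.5, 100_001)
        dens = np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2).sum(axis=1)
        assert mode == pytest.approx(grid[np.argmax(dens)], abs=2e-3)

    def test_config_errors(self, toy_ds):
        with pytest.raises(ConfigError):
            mode_based(toy_ds, phi=0.0, seed=1)
        with pytest.raises(ConfigError):
            mode_based(toy_ds, n_boot=0, seed=1)


class TestDiagnostics:
    def test_q_zero_when_ratios_identical(self):
        g = np.array([0.1, 0.2, 0.4])
        q, df, p = cochran_q(simple_ds(g, 0.3 * g, np.full(3, 0.02)))
        assert q == pytest.approx(0.0, abs=1e-20)
        assert df == 2
        assert p == pytest.approx(1.0)

    def test_q_matches_direct_sum(self, make_random_dataset, rng):
        ds = make_random_dataset(rng)
        q, df, p = cochran_q(ds)
        w = ds.beta_exp**2 / ds.se_out**2
        b = ds.beta_out / ds.beta_exp
        bivw = np.sum(w * b) / np.sum(w)
        assert q == pytest.approx(np.sum(w * (b - bivw) ** 2))
        assert p == pytest.approx(stats.chi2.sf(q, ds.m - 1))

    def test_mean_f_unit_case(self):
        g = np.array([0.1, 0.2, 0.4])
        ds = simple_ds(g, 0.3 * g, np.full(3, 0.02), se_exp=g)
        assert mean_f_statistic(ds) == pytest.approx(1.0)

    def test_intercept_test(self, make_random_dataset, rng):
        ds = make_random_dataset(rng)
        est = mr_egger(ds)
        z, p = intercept_test(est)
        assert z == pytest.approx(est.intercept / est.se_intercept)
        assert p == pytest.approx(est.p_intercept)
        with pytest.raises(ValidationError):
            intercept_test(ivw(ds))

    def test_zero_intercept_gives_p_one(self, make_random_dataset, rng):
        from dataclasses import replace

        est = replace(mr_egger(make_random_dataset(rng)), intercept=0.0)
        _, p = intercept_test(est)
        assert p == pytest.approx(1.0)


class TestSerialization:
    def test_tidy_frame_and_json(self, make_random_dataset, rng, tmp_path):
        ds = make_random_dataset(rng)
        results = [ivw(ds), mr_egger(ds), mr_grip(ds)]
        frame = estimates_to_frame(results)
        assert list(frame["method"]) == ["ivw", "mr_egger", "mr_grip"]
        assert frame.loc[0, "intercept"] is None or np.isnan(frame.loc[0, "intercept"])
        out = tmp_path / "report.json"
        estimates_to_json(results, out)
        import json

        data = json.loads(out.read_text())
        assert data["results"][2]["beta"] == pytest.approx(results[2].beta)
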