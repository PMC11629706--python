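import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mrgj.estimators import (
    EstimatorError,
    egger,
    ivw,
    mode_estimate,
    wald_ratios,
    wald_summary,
    weighted_median,
)

from conftest import make_harmonized


def ratios_from(theta, se_theta):
    theta = np.asarray(theta, float)
    se_theta = np.broadcast_to(np.asarray(se_theta, float), theta.shape)
    return pd.DataFrame(
        {
            "variant_id": [f"rs{i}" for i in range(len(theta))],
            "theta": theta,
            "se_theta": se_theta,
            "weight": 1 / se_theta**2,
        }
    )


class TestWaldRatios:
    def test_arithmetic(self):
        h = make_harmonized(beta_exp=[0.5], beta_out=[0.25], se_out=0.1)
        r = wald_ratios(h)
        assert r.loc[0, "theta"] == pytest.approx(0.5)
        assert r.loc[0, "se_theta"] == pytest.approx(0.2)

    def test_null_outcome(self):
        r = wald_ratios(make_harmonized(beta_exp=[0.5], beta_out=[0.0], se_out=0.1))
        assert r.loc[0, "theta"] == 0 and np.isfinite(r.loc[0, "se_theta"])

    def test_joint_sign_flip_invariance(self):
        a = wald_ratios(make_harmonized(beta_exp=[0.5], beta_out=[0.25]))
        b = wald_ratios(make_harmonized(beta_exp=[-0.5], beta_out=[-0.25]))
        assert a.loc[0, "theta"] == b.loc[0, "theta"]
        assert a.loc[0, "se_theta"] == b.loc[0, "se_theta"]

    def test_zero_exposure_beta_excluded(self):
        h = make_harmonized(beta_exp=[0.5, 0.0], beta_out=[0.25, 0.1])
        assert len(wald_ratios(h)) == 1


class TestIVW:
    def test_single_ratio_is_wald_estimate(self):
        with pytest.warns(UserWarning, match="single instrument"):
            est = ivw(ratios_from([0.3], [0.1]))
        assert est.beta == pytest.approx(0.3)
        assert est.se == pytest.approx(0.1)

    def test_equal_weights_mean(self):
        est = ivw(ratios_from([0.2, 0.4], [0.1, 0.1]), effects_model="fixed")
        assert est.beta == pytest.approx(0.3)

    def test_empty_input_errors(self):
        with pytest.raises(EstimatorError):
            ivw(ratios_from([], []))

    def test_equals_wls_through_origin(self, rng):
        """IVW == weighted least squares of beta_out on beta_exp through origin."""
        import statsmodels.api as sm

        for _ in range(20):
            j = int(rng.integers(3, 12))
            h = make_harmonized(
                beta_exp=rng.normal(0.2, 0.1, j),
                beta_out=rng.normal(0.1, 0.1, j),
                se_out=rng.uniform(0.02, 0.2, j),
            )
            r = wald_ratios(h)
            mine = ivw(r, effects_model="fixed")
            w = 1 / h.table["se_out"] ** 2
            fit = sm.WLS(h.table["beta_out"], h.table["beta_exp"], weights=w).fit()
            assert mine.beta == pytest.approx(fit.params.iloc[0], abs=1e-10)
            assert mine.se == pytest.approx(
                float(fit.bse.iloc[0]) / np.sqrt(fit.scale), abs=1e-10
            )

    def test_random_effects_never_narrower_than_fixed(self, rng):
        r = ratios_from(rng.normal(0.3, 0.5, 10), rng.uniform(0.05, 0.2, 10))
        assert ivw(r, "multiplicative_random").se >= ivw(r, "fixed").se


class TestEgger:
    def test_noiseless_linear_recovery(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        by = 0.05 + 0.8 * bx
        h = make_harmonized(beta_exp=bx, beta_out=by, se_out=0.05)
        slope, intercept = egger(h)
        assert slope.beta == pytest.approx(0.8, abs=1e-12)
        assert intercept["estimate"] == pytest.approx(0.05, abs=1e-12)

    def test_matches_normal_equations(self, rng):
        """Weighted normal equations solved independently agree to 1e-10."""
        j = 15
        bx = np.abs(rng.normal(0.2, 0.1, j))
        by = 0.02 + 0.5 * bx + rng.normal(0, 0.05, j)
        se_out = rng.uniform(0.02, 0.1, j)
        h = make_harmonized(beta_exp=bx, beta_out=by, se_out=se_out)
        slope, intercept = egger(h)
        w = 1 / se_out**2
        X = np.column_stack([np.ones(j), bx])
        coef = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * by))
        assert intercept["estimate"] == pytest.approx(coef[0], abs=1e-10)
        assert slope.beta == pytest.approx(coef[1], abs=1e-10)

    def test_orientation_invariance(self, rng):
        """Negating both betas of any SNP leaves the Egger fit unchanged."""
        j = 10
        bx = rng.normal(0.2, 0.1, j)
        by = 0.03 + 0.4 * bx + rng.normal(0, 0.02, j)
        h1 = make_harmonized(beta_exp=bx, beta_out=by, se_out=0.05)
        flip = rng.random(j) < 0.5
        sign = np.where(flip, -1.0, 1.0)
        h2 = make_harmonized(beta_exp=sign * bx, beta_out=sign * by, se_out=0.05)
        s1, i1 = egger(h1)
        s2, i2 = egger(h2)
        assert s1.beta == pytest.approx(s2.beta, abs=1e-12)
        assert i1["estimate"] == pytest.approx(i2["estimate"], abs=1e-12)

    def test_collinear_exposures_error(self):
        h = make_harmonized(beta_exp=[0.2, 0.2, 0.2], beta_out=[0.1, 0.12, 0.08])
        with pytest.raises(EstimatorError, match="identical"):
            egger(h)

    def test_too_few_instruments(self):
        with pytest.raises(EstimatorError, match="at least 3"):
            egger(make_harmonized(beta_exp=[0.1, 0.2], beta_out=[0.1, 0.1]))

    def test_balanced_pleiotropy_mean_intercept_near_zero(self, rng):
        """Across replicates with balanced pleiotropy the intercept centres on 0."""
        ests = []
        for _ in range(300):
            j = 20
            bx = rng.normal(0.25, 0.1, j)
            alpha = rng.normal(0.0, 0.05, j)
            by = alpha + 0.3 * bx + rng.normal(0, 0.03, j)
            _, intercept = egger(make_harmonized(beta_exp=bx, beta_out=by, se_out=0.03))
            ests.append(intercept["estimate"])
        mc_se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests)) < 3 * mc_se + 1e-12


class TestWeightedMedian:
    def test_equal_weights_is_median(self):
        est = weighted_median(ratios_from([1.0, 2.0, 3.0], 1.0), n_boot=200, seed=1)
        assert est.beta == pytest.approx(2.0)

    def test_even_count_interpolates(self):
        est = weighted_median(ratios_from([1.0, 2.0, 3.0, 4.0], 1.0), n_boot=200, seed=1)
        assert est.beta == pytest.approx(2.5)

    def test_majority_weight_anchors(self):
        r = ratios_from([0.5, 2.0, 3.0], [0.05, 1.0, 1.0])  # first carries ~99% weight
        est = weighted_median(r, n_boot=200, seed=1)
        assert abs(est.beta - 0.5) < 0.8  # inside the interpolation neighbourhood

    def test_small_bootstrap_warns(self):
        with pytest.warns(UserWarning, match="n_boot"):
            weighted_median(ratios_from([1.0, 2.0, 3.0], 1.0), n_boot=50, seed=1)
        with pytest.raises(EstimatorError):
            weighted_median(ratios_from([1.0, 2.0, 3.0], 1.0), n_boot=1, seed=1)

    def test_bootstrap_se_reproducible(self):
        r = ratios_from([0.2, 0.5, 0.8, 0.4], 0.1)
        a = weighted_median(r, n_boot=300, seed=7)
        b = weighted_median(r, n_boot=300, seed=7)
        assert a.se == b.se


class TestMode:
    def test_degenerate_all_equal(self):
        with pytest.warns(UserWarning, match="degenerate"):
            est = mode_estimate(ratios_from([0.7, 0.7, 0.7], 0.1), n_boot=200, seed=1)
        assert est.beta == 0.7 and est.se == 0.0

    def test_cluster_beats_outliers(self):
        theta = [0.5] * 8 + [2.0, 2.0]
        est = mode_estimate(ratios_from(theta, 0.1), n_boot=200, seed=1)
        sd = np.std(theta, ddof=1)
        iqr = np.subtract(*np.percentile(theta, [75, 25]))
        h = 0.9 * min(sd, iqr / 1.349 if iqr > 0 else sd) * len(theta) ** (-0.2)
        assert abs(est.beta - 0.5) <= h

    def test_phi_bounded_argmax(self, rng):
        theta = rng.normal(0.3, 0.2, 12)
        for phi in (0.5, 1.0, 2.0, 4.0):
            est = mode_estimate(ratios_from(theta, 0.1), phi=phi, n_boot=200, seed=1)
            assert theta.min() - 1 <= est.beta <= theta.max() + 1

    def test_weighted_mode_prefers_precise_cluster(self):
        theta = [0.5, 0.52, 0.48, 2.0, 2.01, 1.99]
        se = [0.02, 0.02, 0.02, 1.0, 1.0, 1.0]
        est = mode_estimate(ratios_from(theta, se), weighted=True, n_boot=200, seed=1)
        assert abs(est.beta - 0.5) < 0.3


class TestWaldSummary:
    def test_published_row_back_check(self):
        """A printed (p, OR) pair reproduces its printed CI bounds."""
        beta = np.log(1.63)
        se = beta / stats.norm.isf(0.0018 / 2)
        _, _, pval, (or_, lo, hi) = wald_summary(beta, se)
        assert pval == pytest.approx(0.0018, rel=1e-6)
        assert lo == pytest.approx(1.20, abs=0.03)
        assert hi == pytest.approx(2.22, abs=0.03)

    def test_zero_beta(self):
        ci_low, ci_high, pval, _ = wald_summary(0.0, 0.2)
        assert pval == pytest.approx(1.0)
        assert ci_low == pytest.approx(-ci_high)

    def test_sign_symmetry(self):
        assert wald_summary(0.3, 0.1)[2] == wald_summary(-0.3, 0.1)[2]


@pytest.mark.parametrize("scale", [1.0, 2.0, 0.5])
def test_estimators_equivariant_under_exposure_rescaling(rng, scale):
    """Rescaling exposure betas by c scales every estimate by 1/c."""
    j = 12
    bx = np.abs(rng.normal(0.25, 0.08, j))
    by = 0.4 * bx + rng.normal(0, 0.03, j)
    base = make_harmonized(beta_exp=bx, beta_out=by, se_exp=0.01, se_out=0.03)
    scaled = make_harmonized(beta_exp=scale * bx, beta_out=by, se_exp=0.01 * scale, se_out=0.03)
    r0, r1 = wald_ratios(base), wald_ratios(scaled)
    assert ivw(r1).beta == pytest.approx(ivw(r0).beta / scale, rel=1e-10)
    assert egger(scaled)[0].beta == pytest.approx(egger(base)[0].beta / scale, rel=1e-10)
    assert weighted_median(r1, n_boot=200, seed=3).beta == pytest.approx(
        weighted_median(r0, n_boot=200, seed=3).beta / scale, rel=1e-10
    )
    assert mode_estimate(r1, n_boot=200, seed=3).beta == pytest.approx(
        mode_estimate(r0, n_boot=200, seed=3).beta / scale, rel=0.05
    )


def test_estimators_invariant_under_global_sign_flip(rng):
    """Flipping the sign of every exposure beta leaves estimates unchanged."""
    j = 12
    bx = np.abs(rng.normal(0.25, 0.08, j))
    by = 0.4 * bx + rng.normal(0, 0.03, j)
    a = make_harmonized(beta_exp=bx, beta_out=by, se_out=0.03)
    b = make_harmonized(beta_exp=-bx, beta_out=-by, se_out=0.03)
    ra, rb = wald_ratios(a), wald_ratios(b)
    assert ivw(rb).beta == pytest.approx(ivw(ra).beta, rel=1e-12)
    assert egger(b)[0].beta == pytest.approx(egger(a)[0].beta, rel=1e-12)
    assert weighted_median(rb, n_boot=200, seed=3).beta == pytest.approx(
        weighted_median(ra, n_boot=200, seed=3).beta, rel=1e-12
    )
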