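import numpy as np
import pytest

from conftest import make_harmonized
from mrkit.errors import InsufficientSnpsError
from mrkit.estimators import (
    egger,
    ivw,
    mode_estimate,
    or_from_beta,
    wald_ratio_result,
    wald_ratios,
    weighted_median,
    weighted_median_estimate,
)
from mrkit.instruments import harmonize
from mrkit.simulate import SimulationConfig, simulate_triplet


class TestWaldRatios:
    def test_arithmetic(self):
        h = make_harmonized([0.1], [0.2], se_Gamma=[0.05])
        wr = wald_ratios(h)
        assert wr.beta[0] == pytest.approx(2.0)
        assert wr.se[0] == pytest.approx(0.5)

    def test_zero_numerator(self):
        h = make_harmonized([0.1], [0.0], se_Gamma=[0.05])
        wr = wald_ratios(h)
        assert wr.beta[0] == 0.0
        assert wr.se[0] == pytest.approx(0.5)

    def test_sign(self):
        h = make_harmonized([-0.05], [0.1])
        assert wald_ratios(h).beta[0] == pytest.approx(-2.0)

    def test_zero_gamma_errors(self):
        h = make_harmonized([0.0, 0.1], [0.1, 0.1])
        with pytest.raises(ZeroDivisionError):
            wald_ratios(h)

    def test_single_snp_result(self):
        h = make_harmonized([0.1], [0.2], se_Gamma=[0.05])
        res = wald_ratio_result(h)
        assert res.method == "wald_ratio"
        assert res.beta == pytest.approx(2.0)


class TestIvw:
    def test_equal_weight_mean(self):
        h = make_harmonized([1.0, 1.0], [0.3, 0.5], se_Gamma=[0.1, 0.1])
        assert ivw(h).beta == pytest.approx(0.4)

    def test_perfect_fit_limit(self):
        rng = np.random.default_rng(0)
        gamma = rng.uniform(0.05, 0.2, 10)
        h = make_harmonized(gamma, 0.7 * gamma,
                            se_Gamma=rng.uniform(0.01, 0.05, 10))
        fe = ivw(h, "fixed")
        re = ivw(h, "random")
        assert fe.beta == pytest.approx(0.7, abs=1e-12)
        assert re.extras["q"] == pytest.approx(0.0, abs=1e-18)
        assert fe.se == re.se  # scale floored at 1

    def test_single_snp_refused(self):
        h = make_harmonized([0.1], [0.05])
        with pytest.raises(InsufficientSnpsError, match="wald"):
            ivw(h)

    def test_random_effects_inflates_under_heterogeneity(self, rng):
        j = 40
        gamma = rng.uniform(0.05, 0.2, j)
        Gamma = 0.5 * gamma + rng.normal(0, 0.2, j)
        h = make_harmonized(gamma, Gamma, se_Gamma=np.full(j, 0.02))
        assert ivw(h, "random").se > ivw(h, "fixed").se

    def test_ci_coverage_under_truth(self):
        # no pleiotropy, theta = 0.5: own 95% CI covers truth in >=93% of reps
        hits = 0
        reps = 300
        for seed in range(reps):
            cfg = SimulationConfig(n_snps=50, seed=seed, theta_xz=0.0,
                                   theta_zy=0.0, theta_xy_direct=0.5)
            x, _, y, _, _ = simulate_triplet(cfg)
            h = harmonize(x, y)
            res = ivw(h, "random")
            hits += res.ci_low <= 0.5 <= res.ci_high
        assert hits / reps >= 0.93


class TestEgger:
    def test_exact_affine_recovery(self):
        gamma = np.linspace(0.05, 0.2, 8)
        h = make_harmonized(gamma, 0.02 + 0.5 * gamma)
        res = egger(h)
        assert res.beta == pytest.approx(0.5, abs=1e-10)
        assert res.extras["intercept"] == pytest.approx(0.02, abs=1e-10)
        assert res.extras["q_egger"] == pytest.approx(0.0, abs=1e-16)

    def test_minimal_j3(self):
        h = make_harmonized([0.05, 0.1, 0.15], [0.03, 0.06, 0.08])
        res = egger(h)
        assert np.isfinite(res.se) and np.isfinite(res.extras["intercept_se"])

    def test_orientation_invariance(self, rng):
        j = 12
        gamma = rng.normal(0, 0.1, j)
        gamma[gamma == 0] = 0.05
        Gamma = 0.3 * gamma + rng.normal(0, 0.02, j)
        h1 = make_harmonized(gamma, Gamma)
        flip = rng.choice([1.0, -1.0], j)
        h2 = make_harmonized(gamma * flip, Gamma * flip)
        r1, r2 = egger(h1), egger(h2)
        assert r1.beta == pytest.approx(r2.beta, rel=1e-12)
        assert r1.extras["intercept"] == pytest.approx(r2.extras["intercept"], rel=1e-12)

    def test_too_few_snps(self):
        h = make_harmonized([0.1, 0.2], [0.05, 0.1])
        with pytest.raises(InsufficientSnpsError):
            egger(h)


class TestWeightedMedian:
    def test_equal_weight_median(self):
        est = weighted_median_estimate(np.array([1.0, 2.0, 9.0]), np.ones(3))
        assert est == pytest.approx(2.0)

    def test_full_estimator_median(self):
        # equal gamma and se -> equal weights; ratios (1, 2, 9)
        h = make_harmonized([0.1, 0.1, 0.1], [0.1, 0.2, 0.9],
                            se_Gamma=[0.02, 0.02, 0.02])
        res = weighted_median(h, n_boot=200, seed=1)
        assert res.beta == pytest.approx(2.0)

    def test_seeded_determinism(self, simple_harmonized):
        r1 = weighted_median(simple_harmonized, n_boot=300, seed=11)
        r2 = weighted_median(simple_harmonized, n_boot=300, seed=11)
        assert r1.se == r2.se

    def test_seed_changes_se(self, simple_harmonized):
        r1 = weighted_median(simple_harmonized, n_boot=300, seed=11)
        r2 = weighted_median(simple_harmonized, n_boot=300, seed=12)
        assert r1.se != r2.se

    def test_too_few_snps(self):
        h = make_harmonized([0.1, 0.2], [0.05, 0.1])
        with pytest.raises(InsufficientSnpsError):
            weighted_median(h)


class TestModeEstimate:
    def test_dominant_cluster(self):
        h = make_harmonized([0.1] * 4, [0.05, 0.05, 0.05, 0.5],
                            se_Gamma=[0.02] * 4)
        res = mode_estimate(h, weighted=False, n_boot=100, seed=2)
        assert res.beta == pytest.approx(0.5, abs=0.05)

    def test_degenerate_identical_ratios(self):
        h = make_harmonized([0.1, 0.2, 0.3], [0.05, 0.10, 0.15])
        res = mode_estimate(h, weighted=True, n_boot=100, seed=2)
        assert res.beta == pytest.approx(0.5)
        assert res.extras["bandwidth"] == 0.0

    def test_weighted_mode_recovery_large_j(self):
        cfg = SimulationConfig(n_snps=100, seed=5, n_exposure=200_000,
                               n_outcome=200_000, theta_xy_direct=0.5)
        x, _, y, _, _ = simulate_triplet(cfg)
        h = harmonize(x, y)
        res = mode_estimate(h, weighted=True, n_boot=100, seed=5)
        assert res.beta == pytest.approx(0.5, abs=0.1)

    def test_too_few_snps(self):
        h = make_harmonized([0.1, 0.2], [0.05, 0.1])
        with pytest.raises(InsufficientSnpsError):
            mode_estimate(h)


class TestOrFromBeta:
    def test_paper_shaped_value(self):
        or_, lo, hi = or_from_beta(np.log(0.703), 0.166)
        assert or_ == pytest.approx(0.703)
        assert lo == pytest.approx(np.exp(np.log(0.703) - 1.96 * 0.166))

    def test_zero_beta(self):
        assert or_from_beta(0.0, 0.1)[0] == 1.0

    def test_ln2(self):
        assert or_from_beta(np.log(2), 0.1)[0] == pytest.approx(2.0)

    def test_negative_se_rejected(self):
        with pytest.raises(ValueError):
            or_from_beta(0.1, -0.1)


class TestMrResultInvariants:
    def test_ci_brackets_beta_and_or_consistency(self, simple_harmonized):
        for res in (ivw(simple_harmonized), egger(simple_harmonized)):
            assert res.ci_low < res.beta < res.ci_high
            assert res.or_ == pytest.approx(np.exp(res.beta))
            assert 0 < res.pvalue <= 1
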