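"""Mediation paths, indirect-effect CIs, classification."""

import numpy as np
import pandas as pd
import pytest

from expomic.mediation import (
    MediationModel,
    TripletSpec,
    classify,
    dist_of_product_ci,
    mediate_binary,
    mediate_continuous,
    proportion_mediated,
    select_triplets,
)
from expomic.screen import screen
from expomic.synthetic import SyntheticTruth, generate_mediation_triplet


@pytest.fixture(scope="module")
def continuous_fit():
    truth = SyntheticTruth("t", a=0.5, b=0.4, c_prime=0.3, n=5000, seed=42)
    x, m, y, cov = generate_mediation_triplet(truth)
    return mediate_continuous(x, m, y, cov, n_boot=400, seed=1), truth


class TestContinuous:
    def test_ols_decomposition_identity(self, continuous_fit):
        res, _ = continuous_fit
        assert res.c == pytest.approx(res.c_prime + res.a * res.b, abs=1e-10)

    def test_parameter_recovery(self, continuous_fit):
        res, truth = continuous_fit
        assert res.a == pytest.approx(truth.a, abs=0.06)
        assert res.b == pytest.approx(truth.b, abs=0.06)
        assert res.c_prime == pytest.approx(truth.c_prime, abs=0.06)
        assert res.ab_ci[0] < truth.a * truth.b < res.ab_ci[1]
        assert res.prop_mediated == pytest.approx(
            truth.a * truth.b / (truth.c_prime + truth.a * truth.b), abs=0.05)

    def test_classification_partial(self, continuous_fit):
        res, _ = continuous_fit
        assert res.classification == "partial"

    def test_bootstrap_ci_brackets_estimate(self, continuous_fit):
        res, _ = continuous_fit
        assert res.ab_ci[0] <= res.ab <= res.ab_ci[1]

    def test_null_b_coverage(self):
        covered = 0
        reps = 60
        for seed in range(reps):
            truth = SyntheticTruth("t", a=0.5, b=0.0, c_prime=0.3,
                                   n=400, seed=seed)
            x, m, y, cov = generate_mediation_triplet(truth)
            res = mediate_continuous(x, m, y, cov, n_boot=300, seed=seed)
            covered += res.ab_ci[0] <= 0 <= res.ab_ci[1]
        assert covered >= 0.88 * reps

    def test_deterministic_given_seed(self):
        truth = SyntheticTruth("t", a=0.3, b=0.2, c_prime=0.1, n=300, seed=9)
        x, m, y, cov = generate_mediation_triplet(truth)
        r1 = mediate_continuous(x, m, y, cov, n_boot=200, seed=5)
        r2 = mediate_continuous(x, m, y, cov, n_boot=200, seed=5)
        assert r1.ab_ci == r2.ab_ci

    def test_rank_deficient_design_rejected(self, rng):
        n = 50
        x = rng.standard_normal(n)
        df = pd.DataFrame({"x": x, "m": x, "y": rng.standard_normal(n)})
        model = MediationModel(df, "x", "m", "y", covariates=())
        with pytest.raises((ValueError, AssertionError)):
            model.fit(n_boot=100, seed=0)


class TestBinary:
    def test_recovery_and_scale(self):
        truth = SyntheticTruth("t", a=0.5, b=0.4, c_prime=0.3, n=10000,
                               seed=3, outcome_type="binary")
        x, m, y, cov = generate_mediation_triplet(truth)
        res = mediate_binary(x, m, y, cov, seed=1)
        assert res.method == "dist_of_product"
        assert res.a == pytest.approx(0.5, abs=0.05)
        assert res.b == pytest.approx(0.4, abs=0.1)
        assert res.ab_ci[0] < res.ab < res.ab_ci[1]

    def test_single_class_outcome_rejected(self, rng):
        df = pd.DataFrame({"x": rng.standard_normal(50),
                           "m": rng.standard_normal(50),
                           "y": np.zeros(50)})
        with pytest.raises(ValueError, match="single class"):
            MediationModel(df, "x", "m", "y", outcome_type="binary",
                           covariates=())

    def test_non_01_coding_rejected(self, rng):
        df = pd.DataFrame({"x": rng.standard_normal(50),
                           "m": rng.standard_normal(50),
                           "y": rng.integers(1, 3, 50).astype(float)})
        with pytest.raises(ValueError, match="0/1"):
            MediationModel(df, "x", "m", "y", outcome_type="binary",
                           covariates=())

    def test_perfect_separation_rejected(self):
        n = 60
        x = np.linspace(-3, 3, n)
        df = pd.DataFrame({"x": x, "m": x + 0.01 * np.sin(x),
                           "y": (x > 0).astype(float)})
        model = MediationModel(df, "x", "m", "y", outcome_type="binary",
                               covariates=())
        with pytest.raises(ValueError):
            model.fit(seed=0)


class TestDistOfProduct:
    def test_centered_case_symmetric(self):
        lo, hi = dist_of_product_ci(0.0, 1.0, 0.0, 1.0)
        assert lo == pytest.approx(-hi, abs=1e-6)

    def test_matches_monte_carlo(self):
        r = np.random.default_rng(12)
        a, se_a, b, se_b = 0.5, 0.2, -0.3, 0.15
        lo, hi = dist_of_product_ci(a, se_a, b, se_b)
        draws = r.normal(a, se_a, 2_000_000) * r.normal(b, se_b, 2_000_000)
        mlo, mhi = np.percentile(draws, [2.5, 97.5])
        assert lo == pytest.approx(mlo, abs=0.005)
        assert hi == pytest.approx(mhi, abs=0.005)

    def test_asymptotic_limit_matches_sobel(self):
        # at z = 50 the product distribution is effectively normal
        a, se_a, b, se_b = 50.0, 1.0, 50.0, 1.0
        lo, hi = dist_of_product_ci(a, se_a, b, se_b)
        sobel_sd = np.sqrt(a ** 2 * se_b ** 2 + b ** 2 * se_a ** 2)
        assert lo == pytest.approx(a * b - 1.96 * sobel_sd, rel=0.01)
        assert hi == pytest.approx(a * b + 1.96 * sobel_sd, rel=0.01)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            dist_of_product_ci(np.nan, 1.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            dist_of_product_ci(0.0, -1.0, 0.0, 1.0)


class TestClassify:
    @pytest.mark.parametrize("ab, ci, cp, cpp, expected", [
        (0.02, (0.01, 0.03), 0.2, 0.001, "partial"),
        (-0.02, (-0.03, -0.01), 0.2, 0.001, "inconsistent"),
        (0.02, (0.01, 0.03), 0.2, 0.4, "full"),
        (0.02, (-0.01, 0.03), 0.2, 0.001, "none"),
    ])
    def test_rules(self, ab, ci, cp, cpp, expected):
        assert classify(ab, ci, cp, cpp) == expected

    def test_scale_invariance_of_classification(self, continuous_fit):
        res, _ = continuous_fit
        # rescaling X is absorbed by Z-scoring, so the classification of a
        # refit on rescaled data is unchanged
        truth = SyntheticTruth("t", a=0.5, b=0.4, c_prime=0.3, n=5000, seed=42)
        x, m, y, cov = generate_mediation_triplet(truth)
        res2 = mediate_continuous(x * 7.0, m, y, cov, n_boot=400, seed=1)
        assert res2.classification == res.classification
        assert res2.ab == pytest.approx(res.ab, abs=1e-10)


class TestProportionMediated:
    def test_simple_ratio(self):
        assert proportion_mediated(0.02, 0.2) == (pytest.approx(0.10), "ok")

    def test_negative_flagged(self):
        v, flag = proportion_mediated(-0.01, 0.2)
        assert v == pytest.approx(-0.05)
        assert flag == "out_of_range"

    def test_zero_total_undefined(self):
        v, flag = proportion_mediated(0.02, 0.0)
        assert np.isnan(v) and flag == "undefined"


class TestSelectTriplets:
    def _screens(self):
        r = np.random.default_rng(21)
        n = 2000
        x1 = r.standard_normal(n)
        X = pd.DataFrame({"x1": x1, "x2": r.standard_normal(n)})
        M = pd.DataFrame({
            "m1": 0.5 * x1 + r.standard_normal(n),
            "m2": 0.5 * x1 + r.standard_normal(n),
            "m3": r.standard_normal(n)})
        Y = pd.DataFrame({
            "y1": 0.4 * x1 + r.standard_normal(n),
            "y2": 0.4 * x1 + r.standard_normal(n),
            "y3": 0.4 * x1 + r.standard_normal(n)})
        return screen(X, M), screen(X, Y)

    def test_cartesian_product_per_exposure(self):
        ms, ys = self._screens()
        triplets = select_triplets(ms, ys)
        x1_triplets = [t for t in triplets if t.x == "x1"]
        n_m = len(ms.significant_pairs().query("x == 'x1'"))
        n_y = len(ys.significant_pairs().query("x == 'x1'"))
        assert len(x1_triplets) == n_m * n_y == 6
        assert not [t for t in triplets if t.x == "x2"]

    def test_empty_when_one_side_empty(self):
        ms, ys = self._screens()
        empty = ys.table.copy()
        empty["significant"] = False
        ys_empty = type(ys)(empty, ys.signed_r2 * 0, ys.metadata)
        assert select_triplets(ms, ys_empty) == []

    def test_y_types_propagate(self):
        ms, ys = self._screens()
        triplets = select_triplets(ms, ys, y_types={"y1": "binary"})
        kinds = {t.y: t.y_type for t in triplets}
        assert kinds["y1"] == "binary" and kinds["y2"] == "continuous"
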