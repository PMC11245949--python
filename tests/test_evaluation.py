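import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from nirferm.evaluation import (
    EvaluationError,
    CVReport,
    compare_models,
    compute_metrics,
    ks_statistic,
    plsr_recipe,
    run_repeated_kfold,
)


class TestMetrics:
    def test_hand_computed_example(self):
        # residuals (1, -1, -1, 1): RMSE = 1; y mean 2, TSS = 16 -> R2 = 0.75
        m = compute_metrics([0, 0, 4, 4], [1, -1, 3, 5])
        assert abs(m.rmse - 1.0) < 1e-12
        assert abs(m.r2 - 0.75) < 1e-12
        assert abs(m.sd - 2.0) < 1e-12
        assert abs(m.rpd - 2.0) < 1e-12

    def test_perfect_prediction_flags_rpd(self):
        m = compute_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m.r2 == 1.0 and m.rmse == 0.0
        assert math.isinf(m.rpd) and not m.rpd_defined

    def test_mean_prediction_gives_zero_r2(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        m = compute_metrics(y, np.full(4, y.mean()))
        assert abs(m.r2) < 1e-12

    def test_rpd_rmse_identity(self, rng):
        for _ in range(20):
            y = rng.normal(size=15)
            yhat = y + rng.normal(size=15)
            m = compute_metrics(y, yhat)
            assert abs(m.rpd * m.rmse - m.sd) < 1e-12

    def test_external_sd_reference_used(self):
        m = compute_metrics([0, 0, 4, 4], [1, -1, 3, 5], sd_reference=3.0)
        assert abs(m.rpd - 3.0) < 1e-12

    def test_predicted_denominator_variant(self):
        # retained for audit of the alternative normalisation
        y_true = [0.0, 0.0, 4.0, 4.0]
        y_pred = [1.0, -1.0, 3.0, 5.0]
        m = compute_metrics(y_true, y_pred, r2_denominator="predicted")
        denom = np.sum((np.array(y_pred) - 2.0) ** 2)
        assert abs(m.r2 - (1 - 4.0 / denom)) < 1e-12

    def test_zero_variance_y_rejected(self):
        with pytest.raises(EvaluationError):
            compute_metrics([1.0, 1.0], [1.0, 2.0])


class _MarkerRecipe:
    """Records training markers so the fold protocol can be audited."""

    def __init__(self):
        self.train_markers = []

    def __call__(self, X, y, seed):
        self.train_markers.append(set(X[:, 0].astype(int)))
        return self

    def predict(self, X):
        return X[:, 1]


class TestRepeatedKFold:
    def make_data(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        X = np.column_stack([np.arange(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        return X, y

    def test_each_sample_held_out_once_per_repetition(self):
        n, k, reps = 20, 5, 3
        X, y = self.make_data(n)
        recipe = _MarkerRecipe()
        run_repeated_kfold(X, y, recipe, k=k, reps=reps, base_seed=9)
        assert len(recipe.train_markers) == k * reps
        for rep in range(reps):
            folds = recipe.train_markers[rep * k : (rep + 1) * k]
            held_out = [set(range(n)) - train for train in folds]
            # disjoint folds whose union is the whole sample
            assert sum(len(f) for f in held_out) == n
            assert set().union(*held_out) == set(range(n))

    def test_bit_reproducible_from_base_seed(self, small_absorbance, small_benchmark):
        X = small_absorbance.values
        y = small_benchmark.ph_ref.y
        a = run_repeated_kfold(X, y, plsr_recipe(4), k=5, reps=2, base_seed=3)
        b = run_repeated_kfold(X, y, plsr_recipe(4), k=5, reps=2, base_seed=3)
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_leave_one_out_boundary(self, rng):
        X = rng.normal(size=(10, 3))
        y = X[:, 0] + 0.1 * rng.normal(size=10)
        report = run_repeated_kfold(X, y, plsr_recipe(2), k=10, reps=1, base_seed=0)
        assert len(report.frame) == 10

    def test_noise_free_linear_data_recovers(self):
        import nirferm as nf

        scenario = nf.small_scenario(seed=5).noiseless()
        b = nf.make_benchmark(scenario)
        spectra = nf.sg_smooth(nf.reflectance_to_absorbance(b.spectra))
        joined = nf.join_dataset(spectra, b.ph_ref)
        report = run_repeated_kfold(
            joined.X, joined.y, plsr_recipe(4), k=5, reps=1, base_seed=1
        )
        assert report.r2_mean >= 0.99

    def test_too_few_samples_rejected(self, rng):
        X = rng.normal(size=(3, 2))
        with pytest.raises(EvaluationError):
            run_repeated_kfold(X, rng.normal(size=3), plsr_recipe(1), k=5, reps=1,
                               base_seed=0)

    def test_report_round_trip(self, tmp_path, rng):
        X = rng.normal(size=(20, 4))
        y = X[:, 0] + 0.2 * rng.normal(size=20)
        report = run_repeated_kfold(X, y, plsr_recipe(2), k=4, reps=2, base_seed=7)
        path = tmp_path / "report.csv"
        report.to_csv(path)
        back = CVReport.from_csv(path)
        assert back.rep_seeds == report.rep_seeds
        assert back.aggregate() == pytest.approx(report.aggregate())


def ks_oracle(x, mu, sigma):
    """Sup-distance via evaluation at a dense grid plus the jump points."""
    x = np.sort(np.asarray(x, dtype=float))
    lo, hi = x[0] - 4 * sigma, x[-1] + 4 * sigma
    candidates = np.concatenate([np.linspace(lo, hi, 20001), x, x - 1e-12])
    ecdf = np.searchsorted(x, candidates, side="right") / x.size
    return float(np.max(np.abs(ecdf - norm.cdf(candidates, mu, sigma))))


class TestKSStatistic:
    def test_single_observation_at_median(self):
        result = ks_statistic([3.7])
        assert result.d_plus == result.d_minus == result.d == 0.5

    def test_exact_quantile_design(self):
        # order statistics at the (i - 1/2)/n quantiles of the tested
        # normal give D = 1/(2n) exactly
        n = 20
        x = norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        result = ks_statistic(x, mean=0.0, sd=1.0)
        assert abs(result.d - 0.025) < 1e-12

    def test_agrees_with_brute_force_sweep(self, rng):
        for _ in range(20):
            x = rng.normal(loc=rng.uniform(-2, 2), scale=rng.uniform(0.5, 2),
                           size=rng.integers(5, 40))
            ours = ks_statistic(x)
            assert abs(ours.d - ks_oracle(x, ours.mean, ours.sd)) < 1e-9

    def test_d_is_max_of_one_sided_statistics(self, rng):
        x = rng.normal(size=30)
        result = ks_statistic(x)
        assert result.d == max(result.d_plus, result.d_minus)
        assert 0 <= result.d <= 1

    def test_affine_invariance(self, rng):
        x = rng.normal(size=25)
        base = ks_statistic(x).d
        for a, b in [(2.0, 1.0), (0.3, -5.0)]:
            assert abs(ks_statistic(a * x + b).d - base) < 1e-10

    def test_zero_spread_rejected(self):
        with pytest.raises(EvaluationError):
            ks_statistic([1.0, 1.0, 1.0])


class TestCompareModels:
    def make_reports(self, base_seed=0):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 6))
        y = X[:, 0] - X[:, 3] + 0.2 * rng.normal(size=30)
        full = run_repeated_kfold(X, y, plsr_recipe(3), k=5, reps=2,
                                  base_seed=base_seed)
        opt = run_repeated_kfold(
            X, y, plsr_recipe(3, indices=np.array([0, 3])), k=5, reps=2,
            base_seed=base_seed,
        )
        return full, opt

    def test_identical_recipes_give_identical_rows(self):
        full, _ = self.make_reports()
        table = compare_models(full, {"again": full})
        cols = ["r2", "rmse", "rpd"]
        assert table.loc[0, cols].tolist() == table.loc[1, cols].tolist()

    def test_full_and_optimized_rows(self):
        full, opt = self.make_reports()
        table = compare_models(full, {"subset": opt},
                               n_variables={"subset": 2}, full_n_variables=6)
        assert list(table["model"]) == ["full", "subset"]
        assert table.loc[1, "n_variables"] == 2

    def test_empty_optimized_map(self):
        full, _ = self.make_reports()
        table = compare_models(full, {})
        assert len(table) == 1 and table.loc[0, "model"] == "full"

    def test_mismatched_fold_seeds_rejected(self):
        full, _ = self.make_reports(base_seed=0)
        _, other = self.make_reports(base_seed=99)
        with pytest.raises(EvaluationError, match="seed"):
            compare_models(full, {"other": other})
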