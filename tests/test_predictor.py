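import numpy as np
import pandas as pd
import pytest

from snpsat.errors import InputError, StateError, UndefinedMetricError
from snpsat.predictor import (
    FEATURES,
    TARGET,
    build_training_table,
    load_models,
    predict_saturated_snps,
    regression_metrics,
    save_models,
    train_models,
)
from snpsat.saturation import SaturationSeries
from snpsat.strain_profiles import StrainAbundance, StrainMetrics
from snpsat.synthetic import simulate_predictor_dataset

SMALL_GRID = {"n_estimators": [100], "max_depth": [None], "min_samples_leaf": [1]}


class TestMetrics:
    def test_perfect_prediction(self):
        m = regression_metrics([1, 2, 3, 4], [1, 2, 3, 4])
        assert (m.rse, m.rae, m.r2) == (0.0, 0.0, 1.0)

    def test_mean_predictor_is_unit_error(self):
        y = np.array([3.0, 5.0, 10.0, 2.0])
        m = regression_metrics(y, np.full_like(y, y.mean()))
        assert m.rse == pytest.approx(1.0)
        assert m.rae == pytest.approx(1.0)
        assert m.r2 == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        # y=(1,2,3), yhat=(1,2,4): SS_res=1, SS_tot=2, |res|=1, |dev|=2
        m = regression_metrics([1, 2, 3], [1, 2, 4])
        assert m.rse == pytest.approx(0.5)
        assert m.rae == pytest.approx(0.5)
        assert m.r2 == pytest.approx(0.5)

    def test_identity_r2_plus_rse(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            y = rng.normal(size=30)
            p = rng.normal(size=30)
            m = regression_metrics(y, p)
            assert m.r2 + m.rse == pytest.approx(1.0, abs=1e-12)

    def test_affine_invariance_of_relative_errors(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=40)
        p = rng.normal(size=40)
        m1 = regression_metrics(y, p)
        a, b = 3.7, -12.0
        m2 = regression_metrics(a * y + b, a * p + b)
        assert m1.rse == pytest.approx(m2.rse)
        assert m1.rae == pytest.approx(m2.rae)
        assert m1.r2 == pytest.approx(m2.r2)

    def test_constant_truth_undefined(self):
        with pytest.raises(UndefinedMetricError):
            regression_metrics([2, 2, 2], [1, 2, 3])


def _verdict(strain, saturated, count):
    return SaturationSeries(
        strain=strain,
        raw_levels=np.array([1.0, 2.0, 3.0]),
        raw_counts=np.array([1.0, 2.0, float(count)]),
        x=np.array([0, 0.5, 1.0]),
        y=np.array([0, 0.5, 1.0]),
        ratios=np.array([1.0, 1.0]),
        saturated=saturated,
        saturated_snp_count=count if saturated else None,
    )


class TestBuildTable:
    def _profiles(self, strains, levels):
        metrics = {}
        abund = {}
        for s in strains:
            for lv in levels:
                metrics[(s, lv)] = StrainMetrics(s, 10.0, 0.9, 50, 0.001)
                abund[(s, lv)] = StrainAbundance(s, 1000, 10000, 0.5)
        return metrics, abund

    def test_counts_saturated_rows_only(self):
        metrics, abund = self._profiles(["a", "b"], [1, 2, 3])
        verdicts = {"a": _verdict("a", True, 80), "b": _verdict("b", False, 0)}
        table = build_training_table(metrics, abund, {"a": 10000, "b": 10000}, verdicts)
        assert len(table) == 3
        assert set(table["strain"]) == {"a"}
        assert (table[TARGET] == 80).all()

    def test_no_saturated_strain_empty(self):
        metrics, abund = self._profiles(["a"], [1, 2])
        table = build_training_table(
            metrics, abund, {"a": 1}, {"a": _verdict("a", False, 0)}
        )
        assert table.empty

    def test_missing_verdict_errors(self):
        metrics, abund = self._profiles(["a"], [1])
        with pytest.raises(InputError, match="a"):
            build_training_table(metrics, abund, {"a": 1}, {})


class TestTrain:
    def test_too_few_rows(self):
        rows = simulate_predictor_dataset(30, seed=1).head(10)
        with pytest.raises(InputError):
            train_models(rows)

    def test_noiseless_linear_exact(self):
        rows = simulate_predictor_dataset(120, "linear", noise_sd=0.0, seed=5)
        models = train_models(rows, seed=5, grid=SMALL_GRID)
        assert models.linear_metrics.rse <= 1e-6
        assert models.linear_metrics.r2 >= 1 - 1e-6

    def test_forest_importances_valid_and_top2(self):
        rows = simulate_predictor_dataset(400, "nonlinear", noise_sd=0.05, seed=7)
        models = train_models(rows, seed=7, grid=SMALL_GRID)
        imp = models.feature_importances
        assert (imp >= 0).all()
        assert imp.sum() == pytest.approx(1.0, abs=1e-9)
        top2 = {FEATURES[i] for i in np.argsort(imp)[-2:]}
        assert top2 == {"snp_count", "snp_density"}

    def test_deterministic_for_seed(self):
        rows = simulate_predictor_dataset(100, "nonlinear", seed=3)
        m1 = train_models(rows, seed=3, grid=SMALL_GRID)
        m2 = train_models(rows, seed=3, grid=SMALL_GRID)
        assert m1.forest_metrics.r2 == m2.forest_metrics.r2
        assert (m1.feature_importances == m2.feature_importances).all()


@pytest.fixture(scope="module")
def trained():
    rows = simulate_predictor_dataset(500, "nonlinear", noise_sd=0.02, seed=42)
    return rows, train_models(rows, seed=42, grid=SMALL_GRID)


class TestPredict:

    def test_known_generator_target_within_20pct(self, trained):
        rows, models = trained
        errs = []
        for _, row in rows.tail(50).iterrows():
            pred, _ = predict_saturated_snps(models, row[list(FEATURES)].to_dict())
            errs.append(abs(pred - row["target_truth"]) / row["target_truth"])
        assert np.median(errs) <= 0.20

    def test_all_zero_features_finite(self, trained):
        _, models = trained
        pred, flagged = predict_saturated_snps(models, {f: 0.0 for f in FEATURES})
        assert np.isfinite(pred) and pred >= 0

    def test_below_current_count_flagged(self, trained):
        _, models = trained
        feats = {f: 0.0 for f in FEATURES}
        feats["snp_count"] = 1e12  # absurd current count forces the misfit flag
        _, flagged = predict_saturated_snps(models, feats)
        assert flagged

    def test_missing_feature_rejected(self, trained):
        _, models = trained
        with pytest.raises(InputError):
            predict_saturated_snps(models, {"coverage": 1.0})

    def test_untrained_state_error(self):
        with pytest.raises(StateError):
            predict_saturated_snps(None, {})


def test_save_load_roundtrip(tmp_path):
    rows = simulate_predictor_dataset(60, "nonlinear", seed=9)
    models = train_models(rows, seed=9, grid=SMALL_GRID)
    save_models(models, str(tmp_path / "model"))
    back = load_models(str(tmp_path / "model"))
    assert back.feature_order == models.feature_order
    assert back.forest_metrics.r2 == pytest.approx(models.forest_metrics.r2)
    x = rows.iloc[0][list(FEATURES)].to_dict()
    p1, _ = predict_saturated_snps(models, x)
    p2, _ = predict_saturated_snps(back, x)
    assert p1 == pytest.approx(p2)
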