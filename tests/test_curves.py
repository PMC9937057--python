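"""Learning-curve stage: standardization, exponential fits, feature matrix,
divergence flagging and fit QC."""

import numpy as np
import pandas as pd
import pytest

import climblearn as cl
from climblearn.curves import ExpFit, MetricSeries, fit_qc
from climblearn.pipeline import _dataset_series, exclude_divergent, fit_cohort


def _series(values, metric="GE", pid="p1", t=None):
    values = np.asarray(values, float)
    t = np.arange(len(values), dtype=float) if t is None else t
    return MetricSeries(pid, metric, t, values)


def _cohort_series(seed=0, n=6, noise=0.05):
    config = cl.ProtocolConfig(group_sizes={"CP": n})
    prior = cl.LatentPrior(b_mean=0.08, b_sd=0.02, noise_sd=noise)
    ds = cl.generate_dataset(config, prior, seed=seed, point_rate=0, block_rate=0)
    return ds, _dataset_series(ds)


class TestStandardize:
    def test_pooled_zscore_property(self):
        _, series = _cohort_series()
        std, _, _ = cl.standardize(series)
        for m in cl.METRICS:
            pooled = np.concatenate([s.values for s in std if s.metric == m])
            assert np.nanmean(pooled) == pytest.approx(0.0, abs=1e-12)
            assert np.nanstd(pooled) == pytest.approx(1.0, abs=1e-12)

    def test_idempotence_and_round_trip(self):
        _, series = _cohort_series()
        std, _, params = cl.standardize(series)
        std2, _, params2 = cl.standardize(std)
        for s1, s2 in zip(std, std2):
            np.testing.assert_allclose(s1.values, s2.values, atol=1e-12)
        for s_raw, s_std in zip(series, std):
            back = params.invert_series(s_std)
            np.testing.assert_allclose(back.values, s_raw.values, atol=1e-12)

    def test_targets_standardized(self):
        ds, series = _cohort_series()
        _, transfer, _ = cl.standardize(series, ds.transfer_frame())
        for col in cl.TARGET_COLUMNS:
            assert transfer[col].mean() == pytest.approx(0.0, abs=1e-12)
            assert transfer[col].std(ddof=0) == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_metric_rejected(self):
        bad = [_series(np.full(10, 2.0), "JE"), _series(np.arange(10.0), "GE")]
        with pytest.raises(cl.ConfigurationError, match="JE"):
            cl.standardize(bad)


class TestFitExponential:
    def test_noiseless_recovery(self):
        t = np.arange(84.0)
        fit = cl.fit_exponential(_series(1.0 + 2.0 * np.exp(-0.2 * t)))
        assert fit.converged
        assert fit.a == pytest.approx(1.0, abs=1e-4)
        assert fit.b == pytest.approx(0.2, abs=1e-4)
        assert fit.c == pytest.approx(2.0, abs=1e-4)
        assert fit.mse < 1e-12

    def test_recovery_with_missing_points(self):
        t = np.arange(84.0)
        v = 1.0 + 2.0 * np.exp(-0.2 * t)
        v[::5] = np.nan  # 20% of trials void
        fit = cl.fit_exponential(_series(v))
        assert fit.a == pytest.approx(1.0, abs=1e-4)
        assert fit.b == pytest.approx(0.2, abs=1e-4)

    def test_constant_series_convention(self):
        fit = cl.fit_exponential(_series(np.full(20, 3.5)))
        assert (fit.a, fit.b, fit.c, fit.mse) == (3.5, 0.0, 0.0, 0.0)
        assert fit.converged

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            cl.fit_exponential(_series([1.0, 2.0, 3.0]))

    def test_never_worse_than_constant_model(self, rng):
        t = np.arange(84.0)
        for _ in range(20):
            v = rng.normal(size=84) + rng.uniform(0, 2) * np.exp(-rng.uniform(0.01, 1) * t)
            fit = cl.fit_exponential(_series(v))
            assert fit.mse <= np.var(v) + 1e-12

    def test_e_is_exactly_c_exp_minus_b(self, rng):
        t = np.arange(84.0)
        for _ in range(10):
            v = 1 + 2 * np.exp(-0.1 * t) + rng.normal(0, 0.1, 84)
            fit = cl.fit_exponential(_series(v))
            assert fit.e == fit.c * np.exp(-fit.b)

    def test_parameter_recovery_under_noise(self):
        ds, series = _cohort_series(seed=2, n=30, noise=0.05)
        truth = ds.truth()
        err_a, err_e = [], []
        for s in series:
            fit = cl.fit_exponential(s)
            if not fit.converged:
                continue
            tr = truth[s.participant]
            err_a.append(abs(fit.a - tr["a"][s.metric]))
            err_e.append(abs(fit.e - tr["c"][s.metric] * np.exp(-tr["b"][s.metric])))
        assert np.median(err_a) < 0.05
        assert np.median(err_e) < 0.05


class TestFeatures:
    def test_extract_features_formula(self):
        fit = ExpFit(a=1.0, b=0.2, c=2.0, mse=0.0, converged=True, n_points=84)
        a, e = cl.extract_features(fit)
        assert (a, e) == (1.0, pytest.approx(2 * np.exp(-0.2)))
        zero_rate = ExpFit(a=1.0, b=0.0, c=2.0, mse=0.0, converged=True, n_points=84)
        assert cl.extract_features(zero_rate)[1] == 2.0
        no_amp = ExpFit(a=1.0, b=5.0, c=0.0, mse=0.0, converged=True, n_points=84)
        assert cl.extract_features(no_amp)[1] == 0.0

    def test_non_converged_refused(self):
        bad = ExpFit(a=1e7, b=0.0, c=-1e7, mse=0.1, converged=False, n_points=84)
        with pytest.raises(ValueError):
            cl.extract_features(bad)

    def test_flag_divergent(self):
        good = ExpFit(a=0.0, b=0.1, c=1.0, mse=0.1, converged=True, n_points=84)
        bad = ExpFit(a=1e7, b=0.0, c=-1e7, mse=0.1, converged=False, n_points=84)
        assert cl.flag_divergent({m: good for m in cl.METRICS})
        fits = {m: good for m in cl.METRICS}
        fits["JE"] = bad
        assert not cl.flag_divergent(fits)

    def test_planted_pathological_series_are_excluded(self):
        ds, series = _cohort_series(seed=5, n=8)
        t = np.arange(84.0)
        planted = {"P02", "P05", "P07"}
        growth = np.exp(0.15 * t)
        series = [
            _series((growth - growth.mean()) / growth.std(), s.metric, s.participant)
            if (s.participant in planted and s.metric == "GE")
            else s
            for s in series
        ]
        std, _, _ = cl.standardize(series, ds.transfer_frame())
        fits, _ = fit_cohort(std)
        _, dropped = exclude_divergent(fits)
        assert set(dropped) == planted


class TestFeatureMatrix:
    def test_assembly_shape_and_order(self, small_cohort):
        series = _dataset_series(small_cohort)
        std, transfer, _ = cl.standardize(series, small_cohort.transfer_frame())
        fits, _ = fit_cohort(std)
        kept, _ = exclude_divergent(fits)
        fm = cl.build_feature_matrix(kept, transfer, small_cohort.groups())
        assert fm.X.shape == (13, 8)
        assert list(fm.X.columns) == list(cl.FEATURE_COLUMNS)
        assert list(fm.X.columns)[0] == "a_GE" and list(fm.X.columns)[-1] == "e_CT"
        assert fm.y.shape == (13, 3)
        assert fm.groups.value_counts().to_dict() == {"VP2": 5, "CP": 4, "VP1": 4}

    def test_empty_input_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            cl.build_feature_matrix({}, small_cohort.transfer_frame(), {})

    def test_missing_metric_named(self, small_cohort):
        good = ExpFit(a=0.0, b=0.1, c=1.0, mse=0.1, converged=True, n_points=84)
        fits = {"P01": {m: good for m in ("GE", "JE", "IM")}}  # CT missing
        with pytest.raises(ValueError, match="P01.*CT"):
            cl.build_feature_matrix(fits, small_cohort.transfer_frame(),
                                    small_cohort.groups())

    def test_affine_rescaling_invariance(self):
        ds, series = _cohort_series(seed=9, n=6)
        rescaled = [
            MetricSeries(s.participant, s.metric, s.t, 3.7 * s.values + 11.0)
            if s.metric == "JE" else s
            for s in series
        ]
        fms = []
        for src in (series, rescaled):
            std, transfer, _ = cl.standardize(src, ds.transfer_frame())
            fits, _ = fit_cohort(std)
            kept, _ = exclude_divergent(fits)
            fms.append(cl.build_feature_matrix(kept, transfer, ds.groups()))
        np.testing.assert_allclose(fms[0].X.to_numpy(), fms[1].X.to_numpy(), atol=1e-9)


class TestFitQC:
    @staticmethod
    def _qc_input(mse_complete, mse_incomplete):
        good = lambda mse: ExpFit(a=0, b=0.1, c=1, mse=mse, converged=True, n_points=84)
        fits, complete = {}, {}
        for i, mse in enumerate(mse_complete):
            pid = f"c{i}"
            fits[pid] = {m: good(mse) for m in cl.METRICS}
            complete[pid] = {m: True for m in cl.METRICS}
        for i, mse in enumerate(mse_incomplete):
            pid = f"i{i}"
            fits[pid] = {m: good(mse) for m in cl.METRICS}
            complete[pid] = {m: False for m in cl.METRICS}
        return fits, complete

    def test_identical_distributions_p_one(self):
        fits, complete = self._qc_input([1, 2, 3], [1, 2, 3])
        report = fit_qc(fits, complete)
        for row in report.per_metric:
            assert row.comparison_available
            assert row.mw_p == pytest.approx(1.0)
            assert row.median_mse_complete == row.median_mse_incomplete == 2.0

    def test_tenfold_worse_incomplete_detected(self):
        base = [1.0, 1.3, 0.8, 1.1, 0.9, 1.2, 1.05, 0.95]
        fits, complete = self._qc_input(base, [10 * v for v in base])
        report = fit_qc(fits, complete)
        for row in report.per_metric:
            assert row.mw_p < 0.05

    def test_single_subset_flagged_unavailable(self):
        fits, complete = self._qc_input([1.0, 2.0], [])
        report = fit_qc(fits, complete)
        for row in report.per_metric:
            assert not row.comparison_available
            assert row.mw_p is None
            assert row.median_mse_incomplete is None
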