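"""Splitting protocol, cross-validated factor selection, and the RMSEP/R2
prediction metrics."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fermspec import (
    CalibrationDataset,
    ConcentrationTable,
    ModelSpec,
    NoiseModel,
    SpectraSet,
    compare_models,
    cross_validate,
    evaluate_model,
    fit_on_calibration,
    fit_plsr,
    r_squared,
    rmsep,
    split_dataset,
)
from fermspec.validation import ValidationError


class TestMetrics:
    def test_rmsep_hand_values(self):
        assert rmsep([1, 2, 3], [1, 2, 3]) == 0.0
        assert rmsep([0, 0], [3, 4]) == pytest.approx(np.sqrt(12.5), rel=1e-12)
        # constant offset d comes straight back as |d|
        y = np.array([4.0, 9.0, 1.0])
        assert rmsep(y, y - 2.5) == pytest.approx(2.5, rel=1e-12)

    def test_rmsep_input_validation(self):
        with pytest.raises(ValidationError, match="empty"):
            rmsep([], [])
        with pytest.raises(ValidationError, match="mismatch"):
            rmsep([1, 2], [1])

    def test_r_squared_hand_values(self):
        assert r_squared([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(y, np.full(3, y.mean())) == pytest.approx(0.0,
                                                                   abs=1e-12)
        assert r_squared([1, 2, 3], [1.1, 1.9, 3.2]) == pytest.approx(
            0.97, abs=1e-12)

    def test_r_squared_constant_reference_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            r_squared([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    @settings(max_examples=20, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_rmsep_invariant_under_joint_permutation(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=12)
        yhat = rng.normal(size=12)
        perm = rng.permutation(12)
        assert rmsep(y, yhat) == pytest.approx(rmsep(y[perm], yhat[perm]),
                                               rel=1e-12)


def _dataset_from_arrays(x, conc_values, analytes=("a",)):
    n = x.shape[0]
    ids = [f"s{i:03d}" for i in range(n)]
    spectra = SpectraSet(900.0 + np.arange(x.shape[1], dtype=float), x, ids)
    conc = ConcentrationTable(list(analytes), conc_values, ids)
    return CalibrationDataset(spectra, conc)


class TestSplitDataset:
    def _dataset(self, n, m=2, seed=0):
        rng = np.random.default_rng(seed)
        return _dataset_from_arrays(rng.normal(size=(n, 6)),
                                    rng.uniform(0, 100, (n, m)),
                                    analytes=[f"y{j}" for j in range(m)])

    def test_protocol_sizes_and_extremes(self):
        ds = self._dataset(133)
        plan = split_dataset(ds, prediction_fraction=102 / 133,
                             paper_protocol=True, seed=1)
        assert len(plan.prediction_ids) == 102
        assert len(plan.calibration_ids) == 31
        assert set(plan.prediction_ids) | set(plan.calibration_ids) == \
            set(ds.sample_ids)
        for j, analyte in enumerate(ds.concentrations.analytes):
            col = ds.concentrations.values[:, j]
            for idx in (int(np.argmin(col)), int(np.argmax(col))):
                assert ds.sample_ids[idx] in plan.prediction_ids

    def test_reproducible_under_seed(self):
        ds = self._dataset(40)
        a = split_dataset(ds, 0.6, paper_protocol=False, seed=9)
        b = split_dataset(ds, 0.6, paper_protocol=False, seed=9)
        assert a.prediction_ids == b.prediction_ids

    def test_degenerate_extreme_in_single_sample(self):
        # one analyte constant except a single sample that is both its own
        # min and max neighbourhood: min and max indices coincide
        x = np.random.default_rng(0).normal(size=(10, 4))
        conc = np.ones((10, 1))
        conc[4] = 50.0
        conc2 = np.linspace(0, 1, 10)[:, None]
        ds = _dataset_from_arrays(x, np.hstack([conc, conc2]),
                                  analytes=["spike", "ramp"])
        plan = split_dataset(ds, 0.5, paper_protocol=True, seed=0)
        assert len(plan.prediction_ids) == 5
        assert "s004" in plan.prediction_ids

    def test_bad_fraction_rejected(self):
        ds = self._dataset(10)
        with pytest.raises(ValidationError):
            split_dataset(ds, 0.0)
        with pytest.raises(ValidationError):
            split_dataset(ds, 1.0)


class TestCrossValidate:
    def test_leave_one_out_equals_brute_force_refit(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(12, 6))
        y = rng.normal(size=(12, 1))
        ds = _dataset_from_arrays(x, y)
        report = cross_validate(ds, ModelSpec("plsr"), max_factors=3,
                                scheme="leave_one_out")
        # independent oracle: explicit refit loop
        for k in range(1, 4):
            sq = 0.0
            for i in range(12):
                mask = np.arange(12) != i
                model = fit_plsr(x[mask], y[mask], n_factors=k)
                sq += float((y[i, 0] - model.predict(x[i][None])[0, 0]) ** 2)
            expected = np.sqrt(sq / 12)
            assert report.rmsecv_curve.loc[k, "a"] == pytest.approx(
                expected, abs=1e-10)

    def test_noise_free_three_component_elbow(self, mixture_factory, grid8):
        """RMSECV collapses once the factor count reaches the true chemical
        rank; the parsimony rule then picks exactly that rank (checked over
        ten generator seeds)."""
        hits = 0
        for seed in range(1, 11):
            ds, _ = mixture_factory(grid8, n=40, seed=seed)
            # noise-free data are exactly rank 3, so 3 is the largest
            # feasible factor count
            report = cross_validate(ds, ModelSpec("plsr"), max_factors=3,
                                    scheme="contiguous_blocks", n_blocks=10)
            curve = report.rmsecv_curve["a"]
            hits += (curve.loc[2] >= 10.0 * curve.loc[3]
                     and report.chosen_factors["a"] == 3)
        assert hits >= 9

    def test_chosen_factor_respects_parsimony_rule(self, mixture_factory,
                                                   grid8):
        noise = NoiseModel(additive_sd=0.01, baseline_poly_sd=(0.0,),
                           scatter_sd=0.0, solids_drift_gain=0.0,
                           water_band_extra_sd=0.0)
        ds, _ = mixture_factory(grid8, n=40, seed=3, noise=noise)
        report = cross_validate(ds, ModelSpec("plsr"), max_factors=6)
        for analyte, k in report.chosen_factors.items():
            curve = report.rmsecv_curve[analyte]
            assert curve.loc[k] <= 1.02 * curve.min() + 1e-15

    def test_infeasible_factor_count_rejected(self):
        rng = np.random.default_rng(1)
        ds = _dataset_from_arrays(rng.normal(size=(8, 5)),
                                  rng.normal(size=(8, 1)))
        with pytest.raises(ValidationError, match="infeasible"):
            cross_validate(ds, ModelSpec("plsr"), max_factors=7,
                           scheme="leave_one_out")


class TestEvaluate:
    def test_perfect_model_scores_perfectly(self, mixture3_noise_free):
        ds, _ = mixture3_noise_free
        plan = split_dataset(ds, 0.5, paper_protocol=True, seed=0)
        models, _ = fit_on_calibration(ds, plan, ModelSpec("plsr"),
                                       n_factors=3)
        report = evaluate_model(models, ds, plan)
        for analyte in ds.concentrations.analytes:
            assert report.rmsep[analyte] == pytest.approx(0.0, abs=1e-7)
            assert report.r2[analyte] == pytest.approx(1.0, abs=1e-10)

    def test_report_consistent_with_direct_metric_calls(self,
                                                        mixture_factory,
                                                        grid8):
        noise = NoiseModel(additive_sd=0.01, baseline_poly_sd=(0.01,),
                           scatter_sd=0.01, solids_drift_gain=0.0,
                           water_band_extra_sd=0.0)
        ds, _ = mixture_factory(grid8, n=40, seed=4, noise=noise)
        plan = split_dataset(ds, 0.5, seed=0)
        models, _ = fit_on_calibration(ds, plan, ModelSpec("plsr"),
                                       n_factors=3)
        report = evaluate_model(models, ds, plan)
        pred_ds = ds.subset_ids(plan.prediction_ids)
        for analyte, model in models.items():
            yhat = model.predict(pred_ds.spectra.values).ravel()
            y = pred_ds.concentrations.column(analyte)
            assert report.rmsep[analyte] == pytest.approx(rmsep(y, yhat))
            assert report.r2[analyte] == pytest.approx(r_squared(y, yhat))

    def test_prediction_side_labels_cannot_leak_into_fit(self,
                                                         mixture_factory,
                                                         grid8):
        ds, _ = mixture_factory(grid8, n=30, seed=6)
        plan = split_dataset(ds, 0.5, seed=0)
        models, _ = fit_on_calibration(ds, plan, ModelSpec("plsr"),
                                       n_factors=2)
        # shuffle the prediction-side reference values
        shuffled = ds.concentrations.values.copy()
        pred_pos = [ds.sample_ids.index(s) for s in plan.prediction_ids]
        shuffled[pred_pos] = shuffled[np.random.default_rng(0).permutation(
            pred_pos)]
        ds2 = CalibrationDataset(
            ds.spectra,
            ConcentrationTable(ds.concentrations.analytes, shuffled,
                               ds.sample_ids))
        models2, _ = fit_on_calibration(ds2, plan, ModelSpec("plsr"),
                                        n_factors=2)
        for analyte in models:
            assert np.array_equal(models[analyte].coefficients,
                                  models2[analyte].coefficients)

    def test_unknown_split_ids_rejected(self, mixture3_noise_free):
        ds, _ = mixture3_noise_free
        plan = split_dataset(ds, 0.5, seed=0)
        models, _ = fit_on_calibration(ds, plan, ModelSpec("plsr"),
                                       n_factors=2)
        from fermspec.validation import SplitPlan
        bad = SplitPlan(plan.calibration_ids, ["nope"], "test")
        with pytest.raises(ValidationError, match="unknown ids"):
            evaluate_model(models, ds, bad)

    def test_rapid_substrate_swings_inflate_apparent_error(self, grid8):
        """When reference assays lag the spectra by a fixed sampling delay,
        a pulse-fed substrate (fast swings) shows a larger apparent RMSEP
        than a smoothly varying one at identical instrument noise."""
        from fermspec import generate_pure_spectra, \
            synthesize_from_concentrations
        pure = generate_pure_spectra(["glucose"], grid8, seed=1)
        t = np.arange(0, 96, 1.0)
        smooth = 20.0 + 80.0 * t / 96.0
        pulse = 50.0 - 30.0 * ((t % 12.0) / 12.0)       # sawtooth, 12 h feeds
        noise = NoiseModel(additive_sd=0.002, baseline_poly_sd=(0.0,),
                           scatter_sd=0.0, solids_drift_gain=0.0,
                           water_band_extra_sd=0.0)
        gaps = []
        for profile_name, profile in (("smooth", smooth), ("pulse", pulse)):
            errs = []
            for seed in range(10):
                ids = [f"s{i:03d}" for i in range(t.size)]
                conc_spectra = ConcentrationTable(["glucose"],
                                                  profile[:, None], ids)
                ds = synthesize_from_concentrations(
                    conc_spectra, pure, noise, grid8, seed=seed)
                # the off-line assay is drawn one hour after the spectrum;
                # the final spectrum has no later assay and is dropped
                delayed = profile[1:, None]
                ds = CalibrationDataset(
                    ds.spectra.take(range(t.size - 1)),
                    ConcentrationTable(["glucose"], delayed, ids[:-1]))
                plan = split_dataset(ds, 0.5, paper_protocol=False, seed=seed)
                models, _ = fit_on_calibration(ds, plan, ModelSpec("plsr"),
                                               n_factors=1)
                errs.append(evaluate_model(models, ds, plan).rmsep["glucose"])
            gaps.append(np.mean(errs))
        assert gaps[1] > gaps[0]


class TestCompareModels:
    def test_pcr_with_all_components_equals_mlr(self, mixture_factory, grid8):
        noise = NoiseModel(additive_sd=0.005, baseline_poly_sd=(0.0,),
                           scatter_sd=0.0, solids_drift_gain=0.0,
                           water_band_extra_sd=0.0)
        ds, _ = mixture_factory(grid8, n=40, seed=8, noise=noise)
        plan = split_dataset(ds, 0.5, seed=0)
        n_cal = len(plan.calibration_ids)
        table = compare_models(
            ds,
            [ModelSpec("pcr", {"n_components": n_cal - 1}), ModelSpec("mlr")],
            plan)
        for analyte in ds.concentrations.analytes:
            sub = table[table.analyte == analyte]
            assert sub.rmsep.iloc[0] == pytest.approx(sub.rmsep.iloc[1],
                                                      abs=1e-8)

    def test_identical_specs_give_identical_rows(self, mixture3_noise_free):
        ds, _ = mixture3_noise_free
        plan = split_dataset(ds, 0.5, seed=0)
        table = compare_models(
            ds, [ModelSpec("plsr", {"n_factors": 3}, name="p1"),
                 ModelSpec("plsr", {"n_factors": 3}, name="p2")], plan)
        a = table[table.model == "p1"].sort_values("analyte")
        b = table[table.model == "p2"].sort_values("analyte")
        np.testing.assert_array_equal(a.rmsep.to_numpy(), b.rmsep.to_numpy())

    def test_plsr_beats_unregularised_mlr_on_collinear_spectra(
            self, mixture_factory):
        """Full-wavelength least squares pays a variance penalty on
        collinear spectra (rank-3 signal spread over many noisy channels);
        rank-limited PLS does not."""
        from fermspec import WavelengthGrid
        grid24 = WavelengthGrid.regular(step=32.0)
        noise = NoiseModel(additive_sd=0.02, baseline_poly_sd=(0.02, 0.01),
                           scatter_sd=0.0, solids_drift_gain=0.0,
                           water_band_extra_sd=0.0)
        wins = 0
        for seed in range(10):
            ds, _ = mixture_factory(grid24, n=60, seed=20 + seed, noise=noise)
            plan = split_dataset(ds, 0.5, seed=seed)
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore", RuntimeWarning)
                table = compare_models(
                    ds, [ModelSpec("plsr", {"n_factors": 3}),
                         ModelSpec("mlr")], plan)
            sub = table[table.analyte == "a"].set_index("model")
            wins += (sub.loc["plsr(n_factors=3)", "rmsep"]
                     < sub.loc["mlr", "rmsep"])
        assert wins >= 8

    def test_failures_reported_without_aborting(self, mixture3_noise_free):
        ds, _ = mixture3_noise_free
        plan = split_dataset(ds, 0.5, seed=0)
        table = compare_models(
            ds, [ModelSpec("plsr", {"n_factors": 3}),
                 ModelSpec("plsr", {"n_factors": 500}, name="broken")], plan)
        broken = table[table.model == "broken"]
        assert broken.rmsep.isna().all()
        assert (broken.error != "").all()
        good = table[table.model != "broken"]
        assert good.rmsep.notna().all()
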