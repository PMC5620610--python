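"""Calibration fitting, prediction and QSAR-style validation."""

import numpy as np
import pytest

from glycocal.calibration import (
    CalibrationPoint,
    WeightScheme,
    assemble_training_set,
    fit_cubic,
    fit_svm,
    load_model,
    loo_q2,
    predict_mw,
    save_model,
    y_randomize,
)

SINGLE_COMBO = {"C": (10.0,), "epsilon": (0.01,), "gamma": (0.5,)}


def cubic_points(coeffs, rts, noise=0.0, rng=None):
    rts = np.asarray(rts, dtype=float)
    y = np.polynomial.polynomial.polyval(rts, coeffs)
    if noise:
        y = y + rng.normal(0, noise, rts.size)
    return [CalibrationPoint(mw=10.0**v, rt=float(t), group="G") for v, t in zip(y, rts)]


class TestTrainingSet:
    def test_full_panel_yields_33_weighted_points(self, panel, truth):
        from glycocal.simulate import simulate_standard_rts

        rts = simulate_standard_rts(panel, truth)
        points = assemble_training_set(panel, rts)
        assert len(points) == 33
        weights = {g: {p.weight for p in points if p.group == g} for g in "ABCDEFG"}
        assert weights == {
            "A": {1}, "B": {1}, "C": {2}, "D": {4}, "E": {10}, "F": {10}, "G": {1},
        }
        # the three low-MW outliers are gone but dp4/dp6 remain
        assert sum(1 for p in points if p.group == "A") == 4
        assert sum(1 for p in points if p.group == "B") == 5
        assert sum(1 for p in points if p.group == "F") == 2

    def test_missing_rt_names_compound(self, panel):
        with pytest.raises(KeyError, match="3"):
            assemble_training_set(panel, {})

    def test_custom_weight_scheme(self, panel, truth):
        from glycocal.simulate import simulate_standard_rts

        rts = simulate_standard_rts(panel, truth)
        points = assemble_training_set(panel, rts, WeightScheme({"E": 3.0}))
        assert {p.weight for p in points if p.group == "E"} == {3.0}
        assert {p.weight for p in points if p.group == "D"} == {1.0}


class TestCubic:
    COEFFS = (9.5, -0.7, 0.02, -0.0004)

    def test_noiseless_recovery(self):
        points = cubic_points(self.COEFFS, np.linspace(12, 20, 12))
        model = fit_cubic(points)
        np.testing.assert_allclose(model.coefficients, self.COEFFS, atol=1e-8)
        assert model.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        rts = rng.uniform(12, 20, 10)
        y = rng.uniform(3, 4.2, 10)
        points = [CalibrationPoint(10.0**v, float(t), "G") for v, t in zip(y, rts)]
        model = fit_cubic(points)
        # independent solve of (X'X) a = X'y
        X = np.column_stack([rts**k for k in range(4)])
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(model.coefficients, oracle, atol=1e-8)

    def test_rank_error_below_four_distinct_rts(self):
        pts = [CalibrationPoint(1000.0 * (i + 1), rt, "G") for i, rt in enumerate([1.0, 1.0, 2.0, 3.0])]
        with pytest.raises(ValueError, match="distinct"):
            fit_cubic(pts)

    def test_per_group_fits_on_simulated_standards(self, panel, truth):
        # each structural series follows its own tight calibration line
        from glycocal.simulate import simulate_standard_rts

        rts = simulate_standard_rts(panel, truth)
        for group in "ABCDE":
            pts = [
                CalibrationPoint(r.reported_mw, rts[r.compound_id], group)
                for r in panel
                if r.group == group
            ]
            assert fit_cubic(pts).r_squared > 0.99


class TestSvm:
    def test_weight_equals_replication(self):
        rng = np.random.default_rng(1)
        rts = np.linspace(13, 18, 9)
        y = 7.5 - 0.25 * rts + rng.normal(0, 0.01, rts.size)
        weights = [1, 1, 3, 1, 2, 1, 4, 1, 1]
        weighted = [
            CalibrationPoint(10.0**v, float(t), "G", weight=w)
            for v, t, w in zip(y, rts, weights)
        ]
        replicated = [
            CalibrationPoint(10.0**v, float(t), "G")
            for v, t, w in zip(y, rts, weights)
            for _ in range(w)
        ]
        stats = (float(rts.mean()), float(rts.std()))
        m1 = fit_svm(weighted, grid=SINGLE_COMBO, rt_stats=stats)
        m2 = fit_svm(replicated, grid=SINGLE_COMBO, rt_stats=stats)
        grid = np.linspace(13, 18, 41)
        np.testing.assert_allclose(
            m1.predict_log10_mw(grid), m2.predict_log10_mw(grid), atol=1e-6
        )

    def test_duplicate_rt_pulled_toward_heavier_weight(self):
        # two standards share an RT but differ in MW; the prediction lies
        # between them, closer to the higher-weighted one
        base = [
            CalibrationPoint(10.0 ** (7.5 - 0.25 * t), float(t), "G")
            for t in np.linspace(13, 18, 8)
        ]
        low = CalibrationPoint(2000.0, 15.5, "B", weight=1)
        high = CalibrationPoint(5000.0, 15.5, "E", weight=10)
        model = fit_svm(base + [low, high], grid=SINGLE_COMBO)
        pred = 10.0 ** model.predict_log10_mw(15.5)
        assert low.mw < pred < high.mw
        assert abs(np.log10(pred) - np.log10(high.mw)) < abs(np.log10(pred) - np.log10(low.mw))

    def test_epsilon_tube_on_equal_weights(self):
        pts = [
            CalibrationPoint(10.0 ** (7.5 - 0.25 * t), float(t), "G")
            for t in np.linspace(13, 18, 8)
        ]
        model = fit_svm(pts, grid={"C": (1000.0,), "epsilon": (0.01,), "gamma": (1.0,)})
        for p in pts:
            assert abs(model.predict_log10_mw(p.rt) - np.log10(p.mw)) <= 0.011

    def test_empty_grid_rejected(self, training_points):
        with pytest.raises(ValueError, match="grid"):
            fit_svm(training_points, grid={"C": (), "epsilon": (), "gamma": ()})

    def test_monotone_nonincreasing_over_training_range(self, training_points):
        model = fit_svm(training_points, grid=SINGLE_COMBO)
        lo, hi = model.rt_range
        grid = np.arange(lo, hi, 0.05)
        pred = model.predict_log10_mw(grid)
        # tolerate wiggles up to one grid step of the underlying slope
        assert np.all(np.diff(pred) <= 0.25 * 0.05 + 1e-9)


class TestPredict:
    def test_matches_stored_polynomial(self):
        points = cubic_points(TestCubic.COEFFS, np.linspace(12, 20, 12))
        model = fit_cubic(points)
        grid = np.linspace(12, 20, 30)
        mw, flag = predict_mw(model, grid)
        direct = 10 ** np.polynomial.polynomial.polyval(grid, model.coefficients)
        np.testing.assert_allclose(mw, direct, rtol=1e-9)
        assert not flag.any()

    def test_training_point_recovered(self):
        points = cubic_points(TestCubic.COEFFS, np.linspace(12, 20, 12))
        model = fit_cubic(points)
        mw, flag = predict_mw(model, points[3].rt)
        assert mw == pytest.approx(points[3].mw, rel=1e-3)
        assert flag is False

    def test_extrapolation_flagged(self):
        points = cubic_points(TestCubic.COEFFS, np.linspace(12, 20, 12))
        model = fit_cubic(points)
        _, flag = predict_mw(model, 11.0)
        assert flag is True

    def test_nonfinite_rt_rejected(self):
        model = fit_cubic(cubic_points(TestCubic.COEFFS, np.linspace(12, 20, 12)))
        with pytest.raises(ValueError):
            predict_mw(model, float("nan"))

    def test_serialization_roundtrip(self, tmp_path, training_points):
        for fit in (fit_cubic, lambda p: fit_svm(p, grid=SINGLE_COMBO)):
            model = fit(training_points)
            path = tmp_path / "model.json"
            save_model(model, path)
            back = load_model(path)
            grid = np.linspace(14, 17, 20)
            np.testing.assert_allclose(
                back.predict_log10_mw(grid), model.predict_log10_mw(grid), atol=1e-12
            )


class TestValidation:
    def test_noiseless_cubic_q2_near_one(self):
        points = cubic_points(TestCubic.COEFFS, np.linspace(12, 20, 12))
        assert loo_q2(points, model="cubic").q2 > 0.999

    def test_pure_noise_targets_give_low_q2(self):
        # random MW labels carry no RT relationship; q2 <= 0 in expectation
        q2s = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            rts = np.linspace(12, 20, 10)
            pts = [
                CalibrationPoint(10.0 ** rng.uniform(3, 4), float(t), "G") for t in rts
            ]
            q2s.append(loo_q2(pts, model="cubic").q2)
        assert np.mean(q2s) < 0.2

    def test_zero_variance_rejected(self):
        pts = [CalibrationPoint(1000.0, float(t), "G") for t in np.linspace(12, 20, 6)]
        with pytest.raises(ValueError, match="variance"):
            loo_q2(pts, model="cubic")

    def test_y_randomization_deterministic_and_below_original(self, training_points):
        rep = y_randomize(training_points, model="svm", rounds=5, seed=11, grid=SINGLE_COMBO)
        rep2 = y_randomize(training_points, model="svm", rounds=5, seed=11, grid=SINGLE_COMBO)
        assert rep.y_randomized_q2 == rep2.y_randomized_q2
        assert len(rep.y_randomized_q2) == 5
        assert max(rep.y_randomized_q2) < rep.q2 - 0.5

    def test_identity_permutation_recovers_original_q2(self, training_points):
        rep = loo_q2(training_points, model="svm", grid=SINGLE_COMBO)
        same = [
            CalibrationPoint(p.mw, p.rt, p.group, p.weight) for p in training_points
        ]
        assert loo_q2(same, model="svm", grid=SINGLE_COMBO).q2 == pytest.approx(rep.q2)
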