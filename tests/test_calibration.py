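"""Calibration fitting, figures of merit and inverse prediction."""

import numpy as np
import pytest
from sklearn.base import clone

from padsense import pipeline
from padsense.calibration import (
    LinearCalibration,
    analytical_sensitivity,
    fit_calibration,
    limit_of_detection,
    predict_concentration,
)
from padsense.synth import SynthParams, simulate_calibration_set


def _noise_free_table(concs=(1, 20, 40, 60, 80, 100), reps=2):
    params = SynthParams(noise_sd=0.0, illum_gradient=0.0)
    cs = simulate_calibration_set(list(concs), reps, params)
    return pipeline.extract_calibration_table(cs, params.roi), params


def test_noise_free_fit_is_exact():
    table, params = _noise_free_table()
    model = fit_calibration(table["concentration_umolL"], table["response_norm"])
    assert model.slope_ == pytest.approx(params.slope_m, abs=1e-9)
    assert model.intercept_ == pytest.approx(0.0, abs=1e-7)
    assert model.r_ == pytest.approx(1.0, abs=1e-9)
    assert model.n_points_ == 12


def test_fit_preconditions():
    with pytest.raises(ValueError):
        fit_calibration([10, 20], [8, 16])  # two distinct concentrations
    with pytest.raises(ValueError):
        fit_calibration([10, 10, 10, 10], [8, 8.1, 7.9, 8])  # zero variance
    with pytest.raises(ValueError):
        fit_calibration([1, 2, 3], [1, np.nan, 3])


def test_points_outside_range_are_excluded_and_counted():
    c = np.array([0.0, 1.0, 20.0, 40.0, 150.0])
    y = 0.8 * c
    model = fit_calibration(c, y, linear_range=(1.0, 100.0))
    assert model.n_points_ == 3
    assert model.n_excluded_ == 2
    assert model.slope_ == pytest.approx(0.8)


def test_lod_arithmetic_and_scaling():
    model = LinearCalibration().fit([1, 50, 100], [0.8, 40.0, 80.0])
    assert limit_of_detection(model, 0.0) == 0.0
    assert limit_of_detection(model, 0.1) == pytest.approx(0.375)
    # linear in blank_sd, inverse in slope, over a grid
    for blank_sd in (0.05, 0.1, 0.4):
        for slope in (0.4, 0.8, 1.6):
            m = LinearCalibration().fit([1, 50, 100], np.array([1, 50, 100]) * slope)
            assert m.limit_of_detection(blank_sd) == pytest.approx(3 * blank_sd / slope)


def test_analytical_sensitivity_definition():
    model = LinearCalibration().fit([1, 50, 100], [0.8, 40.0, 80.0])
    reps = [70.0, 72.0, 74.0]  # SD = 2.0
    assert analytical_sensitivity(model, reps) == pytest.approx(0.8 / 2.0)
    with pytest.raises(ValueError):
        analytical_sensitivity(model, [72.0, 72.0, 72.0])
    with pytest.raises(ValueError):
        analytical_sensitivity(model, [72.0])


def test_inverse_prediction_flags():
    model = LinearCalibration(linear_range=(1.0, 100.0)).fit(
        [1, 50, 100], [0.8, 40.0, 80.0]
    )
    model.limit_of_detection(0.1)  # LOD 0.375
    conc, ok = predict_concentration(model, 32.0)
    assert conc == pytest.approx(40.0) and ok
    conc, ok = predict_concentration(model, model.intercept_)
    assert conc == pytest.approx(0.0) and not ok  # below LOD and below range


def test_fit_predict_roundtrip_noise_free():
    table, params = _noise_free_table()
    model = fit_calibration(table["concentration_umolL"], table["response_norm"])
    for c in (5.0, 40.0, 95.0):
        resp = float(model.predict(c))
        back, ok = model.inverse_predict(resp)
        assert back == pytest.approx(c, abs=1e-8)
        assert ok


def test_noisy_recovery_within_5_percent():
    params = SynthParams(seed=5)
    cs = simulate_calibration_set([1, 20, 40, 60, 80, 100], 5, params)
    table = pipeline.extract_calibration_table(cs, params.roi)
    model = fit_calibration(table["concentration_umolL"], table["response_norm"])
    assert model.slope_ == pytest.approx(params.slope_m, rel=0.05)
    assert model.r_ > 0.99


def test_r_degrades_monotonically_with_noise_in_expectation():
    rng_bias = []
    for noise in (0.0, 5.0, 20.0):
        rs = []
        for seed in range(5):
            params = SynthParams(noise_sd=noise, seed=seed)
            cs = simulate_calibration_set([1, 20, 40, 60, 80, 100], 2, params)
            table = pipeline.extract_calibration_table(cs, params.roi)
            m = fit_calibration(table["concentration_umolL"], table["response_norm"])
            rs.append(abs(m.r_))
        rng_bias.append(np.mean(rs))
    assert rng_bias[0] >= rng_bias[1] >= rng_bias[2]


def test_sklearn_estimator_api_roundtrip(tmp_path):
    model = LinearCalibration(linear_range=(2.0, 90.0))
    assert model.get_params() == {"linear_range": (2.0, 90.0)}
    cloned = clone(model).set_params(linear_range=(1.0, 100.0))
    cloned.fit([1, 50, 100], [0.8, 40.0, 80.0])
    cloned.limit_of_detection(0.1)
    path = tmp_path / "cal.yaml"
    cloned.save(path)
    loaded = LinearCalibration.load(path)
    assert loaded.slope_ == cloned.slope_
    assert loaded.lod_ == cloned.lod_
    assert loaded.linear_range == (1.0, 100.0)
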