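"""Generator contracts: determinism, linearity, clipping, recovery."""

import numpy as np
import pytest

from padsense import pipeline
from padsense.imaging import circle_mask
from padsense.stats import group_summary, relative_error
from padsense.synth import (
    CHI3_SD,
    SynthParams,
    pixel_noise_for_blank_sd,
    simulate_calibration_set,
    simulate_interference_set,
    simulate_method_pairs,
    simulate_stability_series,
    simulate_zone_image,
)


def test_zero_concentration_zero_noise_is_pure_receptor(params_clean):
    img, truth = simulate_zone_image(0.0, params_clean)
    mask = circle_mask(img.shape[:2], params_clean.zone_center, params_clean.zone_radius)
    assert np.array_equal(
        img[mask], np.tile(params_clean.receptor_color, (mask.sum(), 1))
    )
    assert np.array_equal(img[~mask], np.tile(params_clean.paper_color, ((~mask).sum(), 1)))
    assert truth.expected_response_norm == 0.0


def test_same_params_same_seed_bit_identical(params_noisy):
    a, _ = simulate_zone_image(40.0, params_noisy, salt=("x",))
    b, _ = simulate_zone_image(40.0, params_noisy, salt=("x",))
    assert np.array_equal(a, b)
    c, _ = simulate_zone_image(40.0, params_noisy, salt=("y",))
    assert not np.array_equal(a, c)


def test_out_of_model_concentration_rejected(params_noisy):
    with pytest.raises(ValueError):
        simulate_zone_image(-1.0, params_noisy)
    with pytest.raises(ValueError):
        simulate_zone_image(params_noisy.conc_max + 1.0, params_noisy)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"zone_radius": 0.0},
        {"noise_sd": -1.0},
        {"illum_gradient": 1.5},
        {"slope_m": 0.0},
        {"receptor_color": (300.0, 0.0, 0.0)},
        {"receptor_color": (250.0, 250.0, 245.0)},  # equals paper
        {"zone_center": (5.0, 5.0)},  # zone leaves the frame
        {"slope_m": 3.0},  # fade overshoots the paper color at conc_max
    ],
)
def test_invalid_params_rejected(kwargs):
    with pytest.raises(ValueError):
        SynthParams(**kwargs)


def test_extracted_norm_matches_truth_at_40(params_noisy):
    """Pipeline-extracted response at 40 µmol/L ≈ slope·c = 32, within the
    averaging-noise tolerance 3·noise_sd·sqrt(2/Npix)."""
    params = SynthParams(illum_gradient=0.0)
    ref, _ = simulate_zone_image(0.0, params, salt=("r",))
    img, truth = simulate_zone_image(40.0, params, salt=("s",))
    norm = pipeline.measure_response(ref, img, params.roi).norm
    n_pix = circle_mask((params.frame_size,) * 2, params.zone_center, params.zone_radius).sum()
    tol = 3 * params.noise_sd * np.sqrt(2.0 / n_pix)
    assert truth.expected_response_norm == 32.0
    assert abs(norm - 32.0) < tol


def test_calibration_set_counts(params_noisy):
    cs = simulate_calibration_set([0, 20, 40, 60, 80, 100], 5, params_noisy)
    assert len(cs.references) == 5
    assert len(cs.responses) == 30
    assert all(cs.responses["truth"].map(lambda t: t.zone_radius == 20.0))
    with pytest.raises(ValueError):
        simulate_calibration_set([], 5, params_noisy)


def test_noise_free_responses_lie_exactly_on_line(params_clean):
    cs = simulate_calibration_set([0, 20, 40, 60, 80, 100], 2, params_clean)
    table = pipeline.extract_calibration_table(cs, params_clean.roi)
    expected = params_clean.slope_m * table["concentration_umolL"]
    assert np.allclose(table["response_norm"], expected, atol=1e-9)


def test_clipping_safety_under_heavy_noise():
    params = SynthParams(noise_sd=80.0, seed=11)
    img, _ = simulate_zone_image(90.0, params)
    assert img.min() >= 0.0 and img.max() <= 255.0


def test_method_pairs_zero_noise_zero_relative_error(params_clean):
    spec = [("g", [42.6, 69.4, 49.1, 55.0, 62.1], 0.0, 0.0, 5)]
    out = simulate_method_pairs(spec, params_clean)
    for row in out.itertuples():
        assert relative_error(row.sensor_mean, row.ref_mean, ndigits=None) == pytest.approx(0.0, abs=1e-9)
    # arithmetic mean recovered through the full image pipeline
    assert group_summary(out["sensor_mean"]).mean == 55.6


def test_method_pairs_reproducible_and_validated(params_noisy):
    spec = [("g", [10.0, 20.0], 0.5, 0.5, 5)]
    a = simulate_method_pairs(spec, params_noisy)
    b = simulate_method_pairs(spec, params_noisy)
    assert a.equals(b)
    with pytest.raises(ValueError):
        simulate_method_pairs([("g", [-1.0], 0.1, 0.1, 5)], params_noisy)
    with pytest.raises(ValueError):
        simulate_method_pairs([("g", [1.0], 0.1, 0.1, 1)], params_noisy)


def test_stability_series_constructed_breakpoint(params_clean):
    flat = simulate_stability_series(10, 10, 0.0, params_clean)
    assert np.allclose(flat["response_norm"], flat["response_norm"].iloc[0], atol=1e-9)
    drift = simulate_stability_series(30, 20, 0.08, params_clean)
    r = drift.set_index("day")["response_norm"]
    assert r[21] < r[20]
    with pytest.raises(ValueError):
        simulate_stability_series(10, 5, -0.1, params_clean)


def test_interference_null_effect_equals_pure_response(params_clean):
    effects = {"Na+": lambda r: 0.0}
    out = simulate_interference_set(40.0, ["Na+"], [20.0, 50.0], effects, params_clean)
    norms = out["response_norm"].to_numpy()
    assert np.allclose(norms, norms[0], atol=1e-9)
    with pytest.raises(ValueError):
        simulate_interference_set(40.0, ["K+"], [20.0], effects, params_clean)
    with pytest.raises(ValueError):
        simulate_interference_set(40.0, ["Na+"], [50.0, 20.0], effects, params_clean)


def test_blank_noise_calibration_inverts(params_noisy):
    """pixel_noise_for_blank_sd targets the blank-response SD it names."""
    target = 0.4 * params_noisy.slope_m / 3.0
    noise = pixel_noise_for_blank_sd(target, params_noisy)
    params = SynthParams(noise_sd=noise)
    sd = pipeline.blank_response_sd(40, params)
    assert sd == pytest.approx(target, rel=0.35)
    # closed-form constant sanity: SD of a standard 3D normal's norm
    assert CHI3_SD == pytest.approx(np.sqrt(3 - 8 / np.pi))
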