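"""Ground-truthed synthetic µPAD data generator.

Every input the analysis pipeline consumes can be generated here: detection
zone photographs, calibration sets, replicate-device panels, stability series,
interference panels and paired sensor/reference determinations.  Each artifact
carries its generating truth so recovery can be tested end to end without any
downloaded data.

Generative color model
----------------------
The detection zone holds a yellow receptor that fades toward the paper
background as the cyanide concentration increases.  The zone's noise-free mean
color moves *linearly along the chord* from ``receptor_color`` to
``paper_color``:

    zone_mean(c) = receptor + (m·c / ‖paper − receptor‖) · (paper − receptor)

so the Euclidean-norm response extracted downstream is exactly ``m·c`` —
the simplest color model consistent with a linear calibration of slope ``m``
(response units per µmol/L).  Nuisance structure is minimal but sufficient to
exercise ROI averaging: i.i.d. per-pixel Gaussian channel noise, a horizontal
linear illumination ramp, and (for multi-device simulations) a multiplicative
between-device response factor with coefficient of variation ``device_rsd``.

Determinism
-----------
Every output is a pure function of its arguments including the seed.  Child
streams are derived from ``SynthParams.seed`` by stable hashing of the calling
context (operation name, concentration, replicate, ...), so each image gets an
independent, reproducible stream.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .imaging import ZoneROI, circle_mask, mean_color
from .response import response_vector

__all__ = [
    "SynthParams",
    "GroundTruth",
    "CalibrationSet",
    "simulate_zone_image",
    "simulate_calibration_set",
    "simulate_replicate_devices",
    "simulate_method_pairs",
    "simulate_stability_series",
    "simulate_interference_set",
    "simulate_optimization_scan",
    "pixel_noise_for_blank_sd",
]

#: Standard deviation of the norm of a standard trivariate normal vector,
#: sqrt(3 - 8/pi).  Used to map a target blank-response SD to a pixel noise SD.
CHI3_SD = float(np.sqrt(3.0 - 8.0 / np.pi))


@dataclass(frozen=True)
class SynthParams:
    """Generative model parameters.

    Defaults are the package's reference study conditions: a yellow receptor
    zone (radius 20 px in a 64 px frame), calibration slope 0.8 response units
    per µmol/L linear up to 100 µmol/L, per-pixel channel noise SD 2, a mild
    2% illumination ramp, and 3.77% between-device response scatter.
    """

    receptor_color: tuple[float, float, float] = (230.0, 200.0, 60.0)
    paper_color: tuple[float, float, float] = (250.0, 250.0, 245.0)
    slope_m: float = 0.8  # response units per µmol/L
    conc_max: float = 100.0  # µmol/L, upper end of linear behaviour
    noise_sd: float = 2.0  # per-pixel per-channel intensity SD
    illum_gradient: float = 0.02  # max fractional intensity change across frame
    zone_center: tuple[float, float] = (32.0, 32.0)  # (row, col) pixels
    zone_radius: float = 20.0  # pixels
    frame_size: int = 64  # pixels (square frame)
    device_rsd: float = 0.0377  # between-device response CV (fractional)
    seed: int = 0

    def __post_init__(self) -> None:
        rec = np.asarray(self.receptor_color, float)
        pap = np.asarray(self.paper_color, float)
        if rec.shape != (3,) or pap.shape != (3,):
            raise ValueError("colors must be 3-vectors")
        if np.any(rec < 0) or np.any(rec > 255) or np.any(pap < 0) or np.any(pap > 255):
            raise ValueError("color components must lie in [0, 255]")
        if np.array_equal(rec, pap):
            raise ValueError("receptor_color must differ from paper_color")
        if not self.slope_m > 0:
            raise ValueError("slope_m must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.illum_gradient < 1:
            raise ValueError("illum_gradient must lie in [0, 1)")
        if self.device_rsd < 0:
            raise ValueError("device_rsd must be non-negative")
        if not self.zone_radius > 0:
            raise ValueError("zone_radius must be positive")
        cr, cc = self.zone_center
        n = self.frame_size
        if (
            cr - self.zone_radius < 0
            or cc - self.zone_radius < 0
            or cr + self.zone_radius > n - 1
            or cc + self.zone_radius > n - 1
        ):
            raise ValueError("detection zone must fit fully inside the frame")
        if self.slope_m * self.conc_max > self.chord_length:
            raise ValueError(
                "slope_m * conc_max exceeds the receptor-to-paper color distance; "
                "the fade would overshoot the paper color"
            )

    @property
    def chord_length(self) -> float:
        return float(
            np.linalg.norm(
                np.asarray(self.paper_color, float) - np.asarray(self.receptor_color, float)
            )
        )

    @property
    def roi(self) -> ZoneROI:
        """The true zone geometry as a fixed-circle ROI."""
        return ZoneROI(self.zone_center, self.zone_radius)


@dataclass(frozen=True)
class GroundTruth:
    """Noise-free truth stored alongside a generated image.

    Never consumed by the pipeline under test; exists only so tests and the
    acceptance script can score recovery.
    """

    concentration: float
    expected_mean_color: tuple[float, float, float]
    expected_response_norm: float
    zone_center: tuple[float, float]
    zone_radius: float


@dataclass
class CalibrationSet:
    """A simulated calibration experiment.

    ``references``: per-replicate blank (concentration 0) images.
    ``responses``: one row per (concentration, replicate) exposure.
    Image columns hold float64 arrays; ``truth`` columns hold GroundTruth.
    """

    references: pd.DataFrame  # columns: replicate, image, truth
    responses: pd.DataFrame  # columns: concentration_umolL, replicate, image, truth


def _child_rng(seed: int, *context) -> np.random.Generator:
    """Independent stream keyed by a stable hash of the calling context."""
    keys = []
    for item in context:
        if isinstance(item, str):
            keys.append(zlib.crc32(item.encode("utf8")))
        elif isinstance(item, float):
            keys.append(zlib.crc32(repr(round(item, 9)).encode("utf8")))
        else:
            keys.append(int(item) & 0xFFFFFFFF)
    ss = np.random.SeedSequence([int(seed) & 0xFFFFFFFF, *keys])
    return np.random.default_rng(ss)


def simulate_zone_image(
    concentration: float, params: SynthParams, *, salt: tuple = ()
) -> tuple[np.ndarray, GroundTruth]:
    """Render one detection-zone photograph at ``concentration`` µmol/L.

    Zone pixels are drawn around the chord color model above; background
    pixels around ``paper_color``.  A horizontal illumination ramp spanning
    ``illum_gradient`` (fractional) is applied, then i.i.d. Gaussian noise of
    SD ``noise_sd``, then values are clipped to [0, 255].  The returned array
    is float64; use :func:`padsense.imaging.save_image` to quantize to PNG.

    ``salt`` distinguishes replicate images that share a concentration.
    """
    if not 0 <= concentration <= params.conc_max:
        raise ValueError(
            f"concentration {concentration} outside the generative model "
            f"[0, {params.conc_max}] µmol/L"
        )
    rec = np.asarray(params.receptor_color, float)
    pap = np.asarray(params.paper_color, float)
    direction = (pap - rec) / params.chord_length
    zone_mean = rec + params.slope_m * concentration * direction

    n = params.frame_size
    mask = circle_mask((n, n), params.zone_center, params.zone_radius)
    img = np.where(mask[..., None], zone_mean, pap)

    if params.illum_gradient:
        ramp = 1.0 + params.illum_gradient * (np.arange(n) / (n - 1) - 0.5)
        img = img * ramp[None, :, None]
    if params.noise_sd:
        rng = _child_rng(params.seed, "zone", float(concentration), *salt)
        img = img + rng.normal(0.0, params.noise_sd, img.shape)
    img = np.clip(img, 0.0, 255.0)

    truth = GroundTruth(
        concentration=float(concentration),
        expected_mean_color=tuple(zone_mean),
        expected_response_norm=params.slope_m * float(concentration),
        zone_center=params.zone_center,
        zone_radius=params.zone_radius,
    )
    return img, truth


def _extracted_norm(
    reference: np.ndarray, response_img: np.ndarray, params: SynthParams
) -> float:
    """Zone-mean Euclidean-norm response of a generated image pair."""
    roi = params.roi
    return response_vector(mean_color(reference, roi), mean_color(response_img, roi)).norm


def simulate_calibration_set(
    conc_list: Sequence[float], n_reps: int, params: SynthParams
) -> CalibrationSet:
    """Simulate a calibration experiment: per-replicate blank references plus
    one response image per (concentration, replicate)."""
    if len(conc_list) == 0:
        raise ValueError("conc_list must not be empty")
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    for c in conc_list:
        if not 0 <= c <= params.conc_max:
            raise ValueError(f"concentration {c} outside [0, {params.conc_max}]")

    ref_rows = []
    for rep in range(1, n_reps + 1):
        img, truth = simulate_zone_image(0.0, params, salt=("ref", rep))
        ref_rows.append({"replicate": rep, "image": img, "truth": truth})

    resp_rows = []
    for c in conc_list:
        for rep in range(1, n_reps + 1):
            img, truth = simulate_zone_image(float(c), params, salt=("cal", rep))
            resp_rows.append(
                {
                    "concentration_umolL": float(c),
                    "replicate": rep,
                    "image": img,
                    "truth": truth,
                }
            )
    return CalibrationSet(pd.DataFrame(ref_rows), pd.DataFrame(resp_rows))


def simulate_replicate_devices(
    concentration: float,
    n_devices: int,
    params: SynthParams,
    device_rsd: float | None = None,
) -> pd.DataFrame:
    """Simulate ``n_devices`` independently fabricated devices exposed to the
    same concentration.

    Each device carries a multiplicative response factor ~ N(1, device_rsd),
    realised as an effective concentration, emulating fabrication variability
    (receptor loading, zone geometry).  Returns one row per device with
    reference/response images and the extracted response norm.
    """
    if n_devices < 1:
        raise ValueError("n_devices must be at least 1")
    rsd = params.device_rsd if device_rsd is None else float(device_rsd)
    if rsd < 0:
        raise ValueError("device_rsd must be non-negative")
    rng = _child_rng(params.seed, "devices", float(concentration))
    factors = rng.normal(1.0, rsd, n_devices) if rsd else np.ones(n_devices)
    rows = []
    for dev, fac in enumerate(factors, 1):
        eff = float(np.clip(concentration * fac, 0.0, params.conc_max))
        ref, _ = simulate_zone_image(0.0, params, salt=("devref", dev))
        resp, truth = simulate_zone_image(eff, params, salt=("dev", dev))
        rows.append(
            {
                "device": dev,
                "reference": ref,
                "response": resp,
                "response_norm": _extracted_norm(ref, resp, params),
                "truth": truth,
            }
        )
    return pd.DataFrame(rows)


def simulate_method_pairs(
    group_spec: Sequence[tuple[str, Sequence[float], float, float, int]],
    params: SynthParams,
    predictor: Callable[[float], float] | None = None,
) -> pd.DataFrame:
    """Simulate paired sensor / reference-method determinations.

    ``group_spec`` rows are ``(group_label, true_concs, sensor_sd, ref_sd,
    n_determinations)`` with SDs in µmol/L, given either as scalars shared by
    the group or as per-sample sequences.  For every sample, sensor
    determinations run through the full image pipeline: the true concentration
    is jittered by N(0, sensor_sd), imaged, zone-averaged, and converted back
    to µmol/L by ``predictor`` (default: the generative line, norm / slope_m).
    Reference determinations are Gaussian draws around the true concentration.

    Returns one row per sample with per-method means and sample SDs.
    """
    if predictor is None:
        predictor = lambda norm: norm / params.slope_m  # noqa: E731
    rows = []
    for label, true_concs, sensor_sd, ref_sd, n_det in group_spec:
        if n_det < 2:
            raise ValueError("n_determinations must be at least 2")
        k = len(true_concs)
        sensor_sds = np.broadcast_to(np.asarray(sensor_sd, float), (k,))
        ref_sds = np.broadcast_to(np.asarray(ref_sd, float), (k,))
        if np.any(sensor_sds < 0) or np.any(ref_sds < 0):
            raise ValueError("method SDs must be non-negative")
        for sample_id, truth in enumerate(true_concs, 1):
            sensor_sd_i = float(sensor_sds[sample_id - 1])
            ref_sd_i = float(ref_sds[sample_id - 1])
            if not truth > 0:
                raise ValueError(f"true concentration must be positive, got {truth}")
            rng = _child_rng(params.seed, "pairs", label, sample_id)
            sensor_vals = []
            for det in range(1, n_det + 1):
                c = float(np.clip(rng.normal(truth, sensor_sd_i), 0.0, params.conc_max))
                ref, _ = simulate_zone_image(0.0, params, salt=("pref", label, sample_id, det))
                resp, _ = simulate_zone_image(c, params, salt=("pair", label, sample_id, det))
                sensor_vals.append(predictor(_extracted_norm(ref, resp, params)))
            ref_vals = rng.normal(truth, ref_sd_i, n_det)
            rows.append(
                {
                    "group": label,
                    "sample_id": sample_id,
                    "true_umolL": float(truth),
                    "sensor_mean": float(np.mean(sensor_vals)),
                    "sensor_sd": float(np.std(sensor_vals, ddof=1)),
                    "ref_mean": float(np.mean(ref_vals)),
                    "ref_sd": float(np.std(ref_vals, ddof=1)),
                    "n": n_det,
                }
            )
    return pd.DataFrame(rows)


def simulate_stability_series(
    n_days: int,
    stable_until_day: int,
    drift_rate: float,
    params: SynthParams,
    concentration: float = 40.0,
) -> pd.DataFrame:
    """Simulate a shelf-stability study: one response per day, days 0..n_days.

    The expected response is constant through ``stable_until_day`` and then
    decays linearly at fractional ``drift_rate`` per day (receptor
    degradation), realised as an effective concentration pushed through the
    image pipeline with the usual pixel noise.
    """
    if n_days < 1:
        raise ValueError("n_days must be at least 1")
    if not 0 <= stable_until_day <= n_days:
        raise ValueError("stable_until_day must lie in [0, n_days]")
    if drift_rate < 0:
        raise ValueError("drift_rate must be non-negative")
    rows = []
    for day in range(n_days + 1):
        frac = 1.0 if day <= stable_until_day else max(
            0.0, 1.0 - drift_rate * (day - stable_until_day)
        )
        eff = concentration * frac
        ref, _ = simulate_zone_image(0.0, params, salt=("stabref", day))
        resp, _ = simulate_zone_image(eff, params, salt=("stab", day))
        rows.append(
            {
                "day": day,
                "response_norm": _extracted_norm(ref, resp, params),
                "true_norm": params.slope_m * eff,
            }
        )
    return pd.DataFrame(rows)


def simulate_interference_set(
    analyte_conc: float,
    species_list: Sequence[str],
    ratio_list: Sequence[float],
    effect_map: Mapping[str, Callable[[float], float]],
    params: SynthParams,
) -> pd.DataFrame:
    """Simulate a selectivity study over foreign-species concentration ratios.

    For each species and each [foreign]/[cyanide] ratio the analyte is imaged
    through the pipeline and the extracted response is perturbed by the
    fractional effect ``effect_map[species](ratio)`` (zero for non-interfering
    species, which must still appear in the map).  A ratio-0 row per species
    records the unperturbed pure-analyte response.
    """
    ratios = list(ratio_list)
    if any(r <= 0 for r in ratios):
        raise ValueError("ratios must be positive")
    if ratios != sorted(ratios):
        raise ValueError("ratios must be sorted ascending")
    rows = []
    for species in species_list:
        if species not in effect_map:
            raise ValueError(f"species {species!r} missing from effect_map")
        effect = effect_map[species]
        for ratio in [0.0, *ratios]:
            ref, _ = simulate_zone_image(0.0, params, salt=("intref", species, ratio))
            resp, _ = simulate_zone_image(analyte_conc, params, salt=("int", species, ratio))
            norm = _extracted_norm(ref, resp, params)
            if ratio > 0:
                norm *= 1.0 + float(effect(ratio))
            rows.append({"species": species, "ratio": float(ratio), "response_norm": norm})
    return pd.DataFrame(rows)


def simulate_optimization_scan(
    levels: Sequence[float],
    relative_profile: Sequence[float],
    params: SynthParams,
    concentration: float = 40.0,
    n_reps: int = 3,
) -> pd.DataFrame:
    """Simulate a single-parameter optimization scan (analyte volume, buffer
    pH, ...): each level attenuates the response by its ``relative_profile``
    entry, with fresh devices per replicate (between-device scatter applies).
    """
    if len(levels) != len(relative_profile):
        raise ValueError("levels and relative_profile must have equal length")
    if len(levels) < 2:
        raise ValueError("need at least 2 levels")
    rows = []
    for level, rel in zip(levels, relative_profile):
        if not 0 <= rel <= 1:
            raise ValueError("relative_profile entries must lie in [0, 1]")
        rng = _child_rng(params.seed, "scan", float(level))
        for rep in range(1, n_reps + 1):
            fac = rng.normal(1.0, params.device_rsd) if params.device_rsd else 1.0
            eff = float(np.clip(concentration * rel * fac, 0.0, params.conc_max))
            ref, _ = simulate_zone_image(0.0, params, salt=("scanref", float(level), rep))
            resp, _ = simulate_zone_image(eff, params, salt=("scan", float(level), rep))
            rows.append(
                {
                    "level": float(level),
                    "replicate": rep,
                    "response_norm": _extracted_norm(ref, resp, params),
                }
            )
    return pd.DataFrame(rows)


def pixel_noise_for_blank_sd(blank_sd: float, params: SynthParams) -> float:
    """Pixel noise SD whose blank-pair response norms have SD ``blank_sd``.

    A blank reference/response pair differs only by averaged pixel noise: each
    zone mean has per-channel SD noise_sd/sqrt(Npix), the channel difference
    has SD noise_sd*sqrt(2/Npix), and the norm of the trivariate Gaussian
    difference has SD CHI3_SD times that.  Inverting gives the pixel noise
    that realises a requested blank-response scatter (e.g. when emulating a
    stated detection limit).
    """
    if blank_sd < 0:
        raise ValueError("blank_sd must be non-negative")
    n_pix = int(circle_mask((params.frame_size,) * 2, params.zone_center, params.zone_radius).sum())
    return blank_sd / (CHI3_SD * np.sqrt(2.0 / n_pix))
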