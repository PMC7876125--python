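"""High-level composition of the analysis stages.

Glue between the generator, the imaging/response extraction, the calibration
and the QC statistics.  The CLI wraps these functions; tests call them
directly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import synth
from .calibration import fit_calibration
from .datasets import GROUP_ORDER, load_method_comparison_panel
from .imaging import ZoneROI, mean_color, save_image
from .interference import tolerance_ratio
from .response import response_vector
from .stats import (
    group_summary,
    relative_error,
    rsd,
    select_optimum,
    stability_check,
    two_sample_t,
)

__all__ = [
    "measure_response",
    "extract_calibration_table",
    "blank_response_sd",
    "compare_methods",
    "run_demo",
]


def measure_response(reference: np.ndarray, response_img: np.ndarray, roi: ZoneROI):
    """Reference/response image pair -> ΔRGB ResponseVector over ``roi``."""
    return response_vector(mean_color(reference, roi), mean_color(response_img, roi))


def extract_calibration_table(
    calset: synth.CalibrationSet, roi: ZoneROI
) -> pd.DataFrame:
    """Extract (concentration, replicate, ΔRGB, norm) rows from a simulated
    calibration set, pairing each response image with its replicate's
    reference."""
    refs = {
        int(row.replicate): mean_color(row.image, roi)
        for row in calset.references.itertuples()
    }
    rows = []
    for row in calset.responses.itertuples():
        vec = response_vector(refs[int(row.replicate)], mean_color(row.image, roi))
        rows.append(
            {
                "concentration_umolL": row.concentration_umolL,
                "replicate": int(row.replicate),
                "dR": vec.dR,
                "dG": vec.dG,
                "dB": vec.dB,
                "response_norm": vec.norm,
            }
        )
    return pd.DataFrame(rows)


def blank_response_sd(
    n_blanks: int, params: synth.SynthParams, roi: ZoneROI | None = None
) -> float:
    """Sample SD of the response norms of ``n_blanks`` blank image pairs."""
    if n_blanks < 2:
        raise ValueError("need at least 2 blank pairs")
    roi = roi or params.roi
    norms = []
    for i in range(n_blanks):
        ref, _ = synth.simulate_zone_image(0.0, params, salt=("blankref", i))
        resp, _ = synth.simulate_zone_image(0.0, params, salt=("blank", i))
        norms.append(measure_response(ref, resp, roi).norm)
    return float(np.std(norms, ddof=1))


def compare_methods(summary: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-sample sensor-vs-reference comparison from summary statistics.

    ``summary`` needs columns group, sample_id, sensor_mean, sensor_sd,
    ref_mean, ref_sd, n.  Adds the pooled t statistic, its two-tailed critical
    value, the significance flag and the relative error (%)."""
    rows = []
    for row in summary.itertuples():
        tt = two_sample_t(
            row.sensor_mean, row.sensor_sd, int(row.n),
            row.ref_mean, row.ref_sd, int(row.n), alpha=alpha,
        )
        out = dict(row._asdict())
        out.pop("Index", None)
        out.update(
            t=tt.t,
            df=tt.df,
            t_critical=tt.t_critical,
            significant=tt.significant,
            relative_error_percent=relative_error(row.sensor_mean, row.ref_mean),
        )
        rows.append(out)
    return pd.DataFrame(rows)


def run_demo(config: dict, outdir: str | Path, write_images: bool = True) -> dict:
    """Run the full synthetic chain and write stage artifacts to ``outdir``.

    Simulates a calibration experiment, fits the calibration line with its
    figures of merit, quantifies a panel of paired sensor/GC-MS samples,
    runs the QC studies (reproducibility, stability, optimization scan,
    interference) and writes CSV/YAML/JSON artifacts.  Returns a summary dict
    with the headline numbers.
    """
    from .config import config_hash  # deferred: config imports nothing from here

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config_hash(config)
    seed = int(config["seed"])
    alpha = float(config["alpha"])
    params = synth.SynthParams(**{**config["synth"], "seed": seed})
    roi_cfg = config["roi"]
    roi = ZoneROI(
        (float(roi_cfg["center_row"]), float(roi_cfg["center_col"])),
        float(roi_cfg["radius_px"]),
    )

    def write_csv(df: pd.DataFrame, name: str, stage: str) -> Path:
        path = outdir / name
        with open(path, "w", newline="") as fh:
            fh.write(
                f"# manifest: stage={stage} version=0.1.0 seed={seed} "
                f"config_sha={cfg_hash}\n"
            )
            df.to_csv(fh, index=False)
        return path

    # 1. calibration experiment -----------------------------------------
    cal_cfg = config["calibration"]
    calset = synth.simulate_calibration_set(
        cal_cfg["concentrations"], int(cal_cfg["n_replicates"]), params
    )
    if write_images:
        imgdir = outdir / "images"
        imgdir.mkdir(exist_ok=True)
        for row in calset.references.itertuples():
            save_image(imgdir / f"reference_rep{row.replicate}.png", row.image)
        for row in calset.responses.itertuples():
            save_image(
                imgdir / f"response_c{row.concentration_umolL:g}_rep{row.replicate}.png",
                row.image,
            )
    cal_table = extract_calibration_table(calset, roi)
    write_csv(cal_table, "responses.csv", "respond")

    model = fit_calibration(
        cal_table["concentration_umolL"], cal_table["response_norm"],
        linear_range=tuple(cal_cfg["range"]),
    )
    blank_sd = blank_response_sd(int(cal_cfg["n_blanks"]), params, roi)
    lod = model.limit_of_detection(blank_sd)
    model.save(outdir / "calibration.yaml")

    conc_pred, in_range = model.inverse_predict(cal_table["response_norm"].to_numpy())
    predictions = cal_table.assign(
        concentration_pred_umolL=conc_pred, in_range=in_range
    )
    write_csv(predictions, "predictions.csv", "quantify")

    # 2. QC studies ------------------------------------------------------
    rep_cfg = config["reproducibility"]
    devices = synth.simulate_replicate_devices(
        float(rep_cfg["concentration"]), int(rep_cfg["n_devices"]), params
    )
    rsd_percent = rsd(devices["response_norm"])

    stab_cfg = config["stability"]
    series = synth.simulate_stability_series(
        int(stab_cfg["n_days"]), int(stab_cfg["stable_until_day"]),
        float(stab_cfg["drift_rate"]), params,
    )
    last_stable = stability_check(
        list(zip(series["day"], series["response_norm"]))
    )

    opt_cfg = config["optimization"]
    scan = synth.simulate_optimization_scan(
        opt_cfg["levels"], opt_cfg["relative_profile"], params,
        n_reps=int(opt_cfg["n_replicates"]),
    )
    optimum = select_optimum(
        opt_cfg["levels"],
        [
            scan.loc[scan["level"] == lvl, "response_norm"].to_numpy()
            for lvl in opt_cfg["levels"]
        ],
    )

    # 3. interference ----------------------------------------------------
    int_cfg = config["interference"]
    tol_by_species = {k: float(v) for k, v in int_cfg["species_tolerance"].items()}
    effect = float(int_cfg["interfering_effect"])
    effects = {
        sp: (lambda ratio, limit=limit: 0.0 if ratio <= limit else effect)
        for sp, limit in tol_by_species.items()
    }
    iset = synth.simulate_interference_set(
        float(int_cfg["analyte_conc"]), list(tol_by_species),
        [float(r) for r in int_cfg["ratios"]], effects, params,
    )
    write_csv(iset, "interference_responses.csv", "interfere")
    tol_rows = []
    for sp in tol_by_species:
        sub = iset[iset["species"] == sp]
        pure = float(sub.loc[sub["ratio"] == 0.0, "response_norm"].iloc[0])
        by_ratio = {
            float(r.ratio): float(r.response_norm)
            for r in sub[sub["ratio"] > 0].itertuples()
        }
        res = tolerance_ratio(pure, by_ratio, species=sp)
        tol_rows.append(
            {
                "species": sp,
                "tolerance_ratio": res.tolerance_ratio,
                "exceeds_max_tested": res.exceeds_max_tested,
            }
        )
    write_csv(pd.DataFrame(tol_rows), "tolerance.csv", "interfere")

    # 4. method comparison on the bundled panel --------------------------
    panel = load_method_comparison_panel()
    group_spec = []
    for group in GROUP_ORDER:
        sub = panel[panel["group"] == group]
        group_spec.append(
            (
                group,
                sub["gcms_mean_umolL"].tolist(),
                sub["sensor_sd_umolL"].tolist(),
                sub["gcms_sd_umolL"].tolist(),
                int(sub["n_determinations"].iloc[0]),
            )
        )
    sim = synth.simulate_method_pairs(
        group_spec, params, predictor=lambda norm: model.inverse_predict(norm)[0]
    )
    comparison = compare_methods(sim, alpha=alpha)
    comparison["recovery_error_percent"] = [
        relative_error(row.sensor_mean, row.true_umolL, ndigits=None)
        for row in comparison.itertuples()
    ]
    comparison["above_lod"] = comparison["sensor_mean"] > lod
    write_csv(comparison, "comparison.csv", "compare")

    means = pd.DataFrame(
        [
            {
                "group": g,
                "mean_umolL": group_summary(
                    comparison.loc[comparison["group"] == g, "sensor_mean"]
                ).mean,
                "sd_umolL": group_summary(
                    comparison.loc[comparison["group"] == g, "sensor_mean"]
                ).sd,
            }
            for g in GROUP_ORDER
        ]
    )
    write_csv(means, "group_means.csv", "compare")

    summary = {
        "slope": model.slope_,
        "intercept": model.intercept_,
        "r": model.r_,
        "lod_umolL": lod,
        "rsd_percent": rsd_percent,
        "last_stable_day": last_stable,
        "optimum_level": optimum,
        "max_recovery_error_percent": float(
            comparison.loc[comparison["above_lod"], "recovery_error_percent"]
            .abs()
            .max()
        ),
        "n_samples": int(len(comparison)),
    }
    with open(outdir / "qc_report.json", "w") as fh:
        json.dump({"manifest": {"seed": seed, "config_sha": cfg_hash}, **summary}, fh, indent=2, sort_keys=True)
    return summary
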