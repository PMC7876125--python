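"""Linear calibration of the Euclidean-norm response with analytical figures
of merit.

The calibration relates the scalar assay response ``y`` (Euclidean-norm
response units) to analyte concentration ``c`` (µmol/L) by ordinary least
squares over a stated linear range:

    y = slope · c + intercept

Figures of merit follow the conventional definitions:

* calibration sensitivity — the slope (response units per µmol/L);
* correlation coefficient — Pearson r of the fitted points;
* limit of detection — LOD = 3·σ_blank / slope, with σ_blank the SD of blank
  (zero-concentration) responses;
* analytical sensitivity γ(c) — slope divided by the replicate response SD at
  concentration c (discriminating power per µmol/L).

Inverse prediction maps a measured response back to concentration,
``c = (y − intercept)/slope``, flagged out-of-range when the estimate falls
outside the linear range or below the LOD.  Responses below the intercept map
to negative concentrations and are reported flagged, not truncated.
"""

from __future__ import annotations

from os import PathLike

import numpy as np
import yaml
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "LinearCalibration",
    "fit_calibration",
    "predict_concentration",
    "limit_of_detection",
    "analytical_sensitivity",
]


class LinearCalibration(RegressorMixin, BaseEstimator):
    """Unweighted OLS calibration line over a linear range.

    Parameters
    ----------
    linear_range : (low, high)
        Concentration window (µmol/L) inside which the response is modelled
        as linear.  Points outside are excluded from the fit and counted in
        ``n_excluded_``.

    Attributes (after ``fit``)
    --------------------------
    slope_ : float
        Calibration sensitivity, response units per µmol/L.
    intercept_ : float
        Response at zero concentration.
    r_ : float
        Pearson correlation coefficient of the fitted points.
    n_points_, n_excluded_ : int
        Points used / excluded by the range filter.
    lod_ : float
        Limit of detection (µmol/L); 0 until :meth:`limit_of_detection` is
        called with a blank SD.

    Replicates enter as individual points, not means.
    """

    def __init__(self, linear_range: tuple[float, float] = (1.0, 100.0)):
        self.linear_range = linear_range

    # -- fitting ---------------------------------------------------------

    def fit(self, X, y):
        low, high = self.linear_range
        if not low < high:
            raise ValueError("linear_range must satisfy low < high")
        c = np.asarray(X, dtype=float).reshape(-1)
        resp = np.asarray(y, dtype=float).reshape(-1)
        if c.shape != resp.shape:
            raise ValueError("X and y must have the same length")
        if not (np.all(np.isfinite(c)) and np.all(np.isfinite(resp))):
            raise ValueError("calibration points must be finite")
        inside = (c >= low) & (c <= high)
        self.n_excluded_ = int((~inside).sum())
        c, resp = c[inside], resp[inside]
        if np.unique(c).size < 3:
            raise ValueError("need at least 3 distinct concentrations in range")
        if np.var(c) == 0:
            raise ValueError("zero concentration variance")
        res = stats.linregress(c, resp)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.r_ = float(res.rvalue)
        self.n_points_ = int(c.size)
        self.lod_ = 0.0
        return self

    # -- forward / inverse prediction -----------------------------------

    def predict(self, X):
        """Expected response at the given concentrations."""
        check_is_fitted(self, "slope_")
        c = np.asarray(X, dtype=float)
        return self.slope_ * c + self.intercept_

    def inverse_predict(self, response):
        """Concentration estimate(s) for measured response(s).

        Returns ``(concentration, in_range)`` where ``in_range`` is False for
        estimates outside the linear range or below the LOD.
        """
        check_is_fitted(self, "slope_")
        if self.slope_ == 0:
            raise ValueError("slope is zero; inverse prediction undefined")
        resp = np.asarray(response, dtype=float)
        conc = (resp - self.intercept_) / self.slope_
        low, high = self.linear_range
        in_range = (conc >= low) & (conc <= high) & (conc >= self.lod_)
        if np.isscalar(response) or resp.ndim == 0:
            return float(conc), bool(in_range)
        return conc, in_range

    # -- figures of merit ------------------------------------------------

    def limit_of_detection(self, blank_sd: float) -> float:
        """LOD = 3 · blank_sd / slope (µmol/L); stored on ``lod_``."""
        check_is_fitted(self, "slope_")
        if self.slope_ <= 0:
            raise ValueError("LOD requires a positive slope")
        if blank_sd < 0:
            raise ValueError("blank_sd must be non-negative")
        self.lod_ = 3.0 * blank_sd / self.slope_
        return self.lod_

    def analytical_sensitivity(self, replicate_responses) -> float:
        """γ = slope / sample SD of replicate responses at one concentration."""
        check_is_fitted(self, "slope_")
        if self.slope_ <= 0:
            raise ValueError("analytical sensitivity requires a positive slope")
        resp = np.asarray(replicate_responses, dtype=float).reshape(-1)
        if resp.size < 2:
            raise ValueError("need at least 2 replicate responses")
        sd = float(np.std(resp, ddof=1))
        if sd == 0:
            raise ValueError("zero replicate SD; analytical sensitivity undefined")
        return self.slope_ / sd

    # -- persistence -----------------------------------------------------

    def to_dict(self) -> dict:
        check_is_fitted(self, "slope_")
        return {
            "slope": self.slope_,
            "intercept": self.intercept_,
            "r": self.r_,
            "linear_range": [float(self.linear_range[0]), float(self.linear_range[1])],
            "lod": self.lod_,
            "n_points": self.n_points_,
            "n_excluded": self.n_excluded_,
        }

    def save(self, path: str | PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "LinearCalibration":
        model = cls(linear_range=tuple(d["linear_range"]))
        model.slope_ = float(d["slope"])
        model.intercept_ = float(d["intercept"])
        model.r_ = float(d["r"])
        model.lod_ = float(d.get("lod", 0.0))
        model.n_points_ = int(d["n_points"])
        model.n_excluded_ = int(d.get("n_excluded", 0))
        return model

    @classmethod
    def load(cls, path: str | PathLike) -> "LinearCalibration":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# Thin functional wrappers ----------------------------------------------


def fit_calibration(
    concentrations, responses, linear_range: tuple[float, float] = (1.0, 100.0)
) -> LinearCalibration:
    return LinearCalibration(linear_range=linear_range).fit(concentrations, responses)


def predict_concentration(model: LinearCalibration, response):
    return model.inverse_predict(response)


def limit_of_detection(model: LinearCalibration, blank_sd: float) -> float:
    return model.limit_of_detection(blank_sd)


def analytical_sensitivity(model: LinearCalibration, replicate_responses) -> float:
    return model.analytical_sensitivity(replicate_responses)
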