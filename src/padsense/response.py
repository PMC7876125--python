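"""The colorimetric response statistic: ΔRGB vector and its Euclidean norm.

The assay signal is the difference between the zone-mean colors of the
reference (before analyte) and response (after analyte) photographs,

    ΔX = X_reference − X_response   for X in {R, G, B},

collapsed to the scalar "pure response" ‖Δ‖ = sqrt(ΔR² + ΔG² + ΔB²).  The norm
is insensitive to the sign convention; the stored component signs follow
reference − response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .imaging import ColorVector

__all__ = ["ResponseVector", "response_vector", "euclidean_norm", "render_difference_map"]


@dataclass(frozen=True)
class ResponseVector:
    dR: float
    dG: float
    dB: float
    norm: float


def euclidean_norm(dR: float, dG: float, dB: float) -> float:
    """sqrt(dR² + dG² + dB²); symmetric in sign and argument order."""
    if not all(math.isfinite(v) for v in (dR, dG, dB)):
        raise ValueError("channel differences must be finite")
    return math.hypot(dR, dG, dB)


def response_vector(reference: ColorVector, response: ColorVector) -> ResponseVector:
    """Per-channel difference reference − response with its Euclidean norm."""
    dR = reference.R - response.R
    dG = reference.G - response.G
    dB = reference.B - response.B
    return ResponseVector(dR, dG, dB, euclidean_norm(dR, dG, dB))


def render_difference_map(
    v: ResponseVector, size: int = 64, gain: float = 1.0
) -> np.ndarray:
    """Render a diagnostic difference map: a filled circle of color
    (|dR|, |dG|, |dB|) × gain on a black field.

    The map mirrors the color-circle visualisation used to present assay
    responses; it is a diagnostic, never an input to downstream statistics.
    """
    if size < 8:
        raise ValueError("size must be at least 8 pixels")
    color = np.clip(gain * np.abs([v.dR, v.dG, v.dB]), 0, 255)
    img = np.zeros((size, size, 3), dtype=float)
    from .imaging import circle_mask  # local import to keep module load light

    mask = circle_mask((size, size), ((size - 1) / 2.0, (size - 1) / 2.0), 0.4 * size)
    img[mask] = color
    return img
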