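"""Weighted region-of-interest aggregation and uncertainty propagation.

Regions are binary masks with optional nonnegative voxel weights (uniform for
plain anatomical ROIs; tractography visitation counts for tract-weighted
regions).  Regional estimates are weighted means with a 95% confidence
half-width based on the weighted standard error with Kish effective sample
size n_eff = (sum w)^2 / (sum w^2).

The regional g-ratio uncertainty is propagated from the v_mwf and v_in
estimates by the first-order delta method on Gamma = (v_mwf/v_in + 1)^-1/2,
with errors treated as independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["WeightedROI", "RegionEstimate", "weighted_mean", "propagate_gratio_uncertainty"]


@dataclass(frozen=True)
class WeightedROI:
    mask: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self):
        mask = np.asarray(self.mask).astype(bool)
        if self.weights is None:
            weights = mask.astype(float)
        else:
            weights = np.asarray(self.weights, dtype=float)
            if weights.shape != mask.shape:
                raise ValueError("weights must share the mask's shape")
            if np.any(weights < 0):
                raise ValueError("weights must be nonnegative")
            weights = np.where(mask, weights, 0.0)
        if weights.sum() <= 0:
            raise ValueError("ROI must have positive total weight")
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "weights", weights)


@dataclass(frozen=True)
class RegionEstimate:
    mean: float
    ci_halfwidth: float
    n_voxels: int

    @classmethod
    def missing(cls) -> "RegionEstimate":
        return cls(np.nan, np.nan, 0)


def weighted_mean(parameter_map: np.ndarray, roi: WeightedROI, ci_level: float = 1.96) -> RegionEstimate:
    """Weighted regional mean with a confidence half-width.

    Missing-value (NaN) voxels are excluded from both the numerator and the
    weight total.  The half-width is ``ci_level`` times the weighted standard
    error sqrt(weighted variance / n_eff); a single valid voxel (or a
    constant map) gives half-width 0.
    """
    parameter_map = np.asarray(parameter_map, dtype=float)
    if parameter_map.shape != roi.mask.shape:
        raise ValueError("map and ROI shapes must match")
    valid = roi.mask & np.isfinite(parameter_map) & (roi.weights > 0)
    if not np.any(valid):
        return RegionEstimate.missing()
    w = roi.weights[valid]
    x = parameter_map[valid]
    wsum = w.sum()
    mean = float(np.sum(w * x) / wsum)
    n_eff = wsum**2 / np.sum(w**2)
    if n_eff <= 1:
        return RegionEstimate(mean, 0.0, int(valid.sum()))
    var = float(np.sum(w * (x - mean) ** 2) / wsum) * n_eff / (n_eff - 1)
    se = np.sqrt(var / n_eff)
    return RegionEstimate(mean, float(ci_level * se), int(valid.sum()))


def propagate_gratio_uncertainty(
    v_mwf: float, sigma_mwf: float, v_in: float, sigma_in: float
) -> tuple[float, float]:
    """Regional g-ratio with first-order (delta-method) uncertainty.

    With Gamma = (1 + m/v)^(-1/2), the analytic partials are
    dGamma/dm = -1/(2v) (1 + m/v)^(-3/2) and
    dGamma/dv = m/(2v^2) (1 + m/v)^(-3/2); variances add assuming
    independent errors in the two regional estimates.
    """
    if sigma_mwf < 0 or sigma_in < 0:
        raise ValueError("sigmas must be nonnegative")
    if not v_in > 0:
        return np.nan, np.nan
    base = (1.0 + v_mwf / v_in) ** -1.5
    d_dm = -0.5 * base / v_in
    d_dv = 0.5 * base * v_mwf / v_in**2
    gamma = (1.0 + v_mwf / v_in) ** -0.5
    sigma = np.sqrt((d_dm * sigma_mwf) ** 2 + (d_dv * sigma_in) ** 2)
    return float(gamma), float(sigma)
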