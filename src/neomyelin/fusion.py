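"""Fusion of relaxometry and diffusion into the four-compartment model.

Multi-echo relaxometry sees all water including the fast-decaying myelin
water; the diffusion signal does not (myelin water T2 is far below the DWI
echo time).  The diffusion fractions v'_in, v'_ex, v'_iso therefore describe
only the DWI-visible pool and are rescaled to fractions of total water by
(1 - v_mwf):

    v_in = v'_in (1 - v_mwf),   and likewise for v_ex, v_iso,

giving the four-compartment decomposition v_mwf + v_in + v_ex + v_iso = 1.
The bulk g-ratio of a voxel (inner axon diameter over myelinated outer
diameter, averaged over the long-cylinder population) follows from the two
volume fractions alone:

    Gamma = (v_mwf / v_in + 1) ** -0.5 .
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "correct_fraction",
    "g_ratio",
    "fuse_maps",
    "myelin_attributable_fraction",
    "myelin_attribution_cohort",
]

#: below this corrected v_in the g-ratio is reported missing (ratio blow-up)
V_IN_FLOOR = 0.01


def correct_fraction(v_prime, v_mwf):
    """Rescale a DWI-visible fraction to a fraction of total water.

    Applies ``v = v' * (1 - v_mwf)``; valid identically for v'_in, v'_ex and
    v'_iso.  Accepts scalars or arrays (NaN passes through).
    """
    v_prime = np.asarray(v_prime, dtype=float)
    v_mwf = np.asarray(v_mwf, dtype=float)
    with np.errstate(invalid="ignore"):
        bad = ((v_prime < 0) | (v_prime > 1) | (v_mwf < 0) | (v_mwf > 1)) & np.isfinite(v_prime) & np.isfinite(v_mwf)
    if np.any(bad):
        raise ValueError("fractions must lie in [0, 1]")
    out = v_prime * (1.0 - v_mwf)
    return float(out) if out.ndim == 0 else out


def g_ratio(v_mwf, v_in, v_in_floor: float = V_IN_FLOOR):
    """Bulk g-ratio ``(v_mwf / v_in + 1) ** -0.5`` from volume fractions.

    Voxels with v_in below ``v_in_floor`` (effectively unmyelinated or empty)
    return NaN rather than raising.  Strictly decreasing in v_mwf at fixed
    v_in; equals 1 when v_mwf = 0.
    """
    v_mwf = np.asarray(v_mwf, dtype=float)
    v_in = np.asarray(v_in, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any((v_mwf < 0) & np.isfinite(v_mwf)):
            raise ValueError("v_mwf must be >= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(v_in >= v_in_floor, (v_mwf / np.where(v_in > 0, v_in, np.nan) + 1.0) ** -0.5, np.nan)
    return float(out) if out.ndim == 0 else out


def fuse_maps(
    relaxometry_maps: dict[str, np.ndarray],
    diffusion_maps: dict[str, np.ndarray],
    mask: np.ndarray,
    v_in_floor: float = V_IN_FLOOR,
) -> dict[str, np.ndarray]:
    """Voxel-wise four-compartment fusion of co-registered parameter maps.

    Expects ``v_mwf`` from relaxometry and the primed fractions from the
    diffusion fit; returns maps of v_mwf, v_in, v_ex, v_iso and g_ratio with
    NaN outside the mask.
    """
    mask = np.asarray(mask).astype(bool)
    v_mwf = np.asarray(relaxometry_maps["v_mwf"], dtype=float)
    shapes = {v_mwf.shape, mask.shape} | {np.asarray(diffusion_maps[k]).shape for k in ("v_in_prime", "v_ex_prime", "v_iso_prime")}
    if len(shapes) != 1:
        raise ValueError("all maps and the mask must share one shape (inputs must be co-registered)")

    out = {}
    m = np.where(mask, v_mwf, np.nan)
    out["v_mwf"] = m
    for prime, name in (("v_in_prime", "v_in"), ("v_ex_prime", "v_ex"), ("v_iso_prime", "v_iso")):
        out[name] = np.where(mask, correct_fraction(diffusion_maps[prime], np.nan_to_num(m, nan=0.0)), np.nan)
    out["g_ratio"] = np.where(mask, g_ratio(np.nan_to_num(m, nan=0.0), out["v_in"], v_in_floor), np.nan)
    return out


def myelin_attributable_fraction(early: tuple, late: tuple) -> float:
    """Share of an intra-axonal change removed by the myelin correction.

    ``early`` and ``late`` are (v'_in, v_in) pairs for the same region at two
    time points.  Returns ``(dv'_in - dv_in) / dv'_in``: the part of the
    apparent (uncorrected) change in intra-axonal fraction that is explained
    by the growth of the myelin water pool.  NaN when the uncorrected change
    is zero.
    """
    dvp = late[0] - early[0]
    dv = late[1] - early[1]
    if dvp == 0:
        return np.nan
    return float((dvp - dv) / dvp)


def myelin_attribution_cohort(table: pd.DataFrame) -> tuple[float, float]:
    """Mean and SD of the myelin-attributable fraction over a cohort.

    ``table`` must hold one row per (subject, scan) with columns ``subject``,
    ``scan`` in {"early", "late"}, ``v_in_prime`` and ``v_in``.
    """
    shares = []
    for _, grp in table.groupby("subject"):
        early = grp[grp["scan"] == "early"].iloc[0]
        late = grp[grp["scan"] == "late"].iloc[0]
        shares.append(
            myelin_attributable_fraction(
                (early["v_in_prime"], early["v_in"]), (late["v_in_prime"], late["v_in"])
            )
        )
    shares = np.asarray(shares, dtype=float)
    return float(np.mean(shares)), float(np.std(shares, ddof=1))
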