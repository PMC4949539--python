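"""Cohort-level developmental statistics.

Regional parameters are modelled as linear functions of equivalent
gestational age (EGA, weeks): ordinary least-squares trend lines with
Pearson correlation and t-distribution p-values, partial correlations that
adjust for covariates (typically EGA) by residualization, and Fisher
z-comparison of two correlation coefficients.  Repeated scans of the same
infant enter cross-sectional trend lines as independent points; a
per-subject two-point rate summary is provided separately for longitudinal
use.

Significance convention: two-sided, alpha = 0.05, no multiplicity
correction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "linear_trend",
    "partial_correlation",
    "compare_fisher",
    "subject_rates",
    "make_cohort_frame",
]


def linear_trend(values: np.ndarray, ega: np.ndarray) -> dict:
    """OLS trend of a parameter on EGA: slope (units/week), r and p."""
    values = np.asarray(values, dtype=float)
    ega = np.asarray(ega, dtype=float)
    if values.size != ega.size or values.size < 3:
        raise ValueError("need matched vectors with n >= 3")
    if np.ptp(ega) == 0:
        return {"slope": np.nan, "intercept": np.nan, "r": np.nan, "p": np.nan, "stderr": np.nan, "n": values.size}
    res = stats.linregress(ega, values)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r": float(res.rvalue),
        "p": float(res.pvalue),
        "stderr": float(res.stderr),
        "n": values.size,
    }


def partial_correlation(x: np.ndarray, y: np.ndarray, covariates: np.ndarray) -> dict:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualized on the covariates (with intercept) by
    OLS; the Pearson correlation of the residuals is returned with a
    t-distribution p-value on n - 2 - k degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    n, k = cov.shape
    if x.size != n or y.size != n:
        raise ValueError("x, y and covariates must have matching length")
    if n <= k + 2:
        raise ValueError("need n > k + 2 observations")
    design = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariates are rank-deficient")
    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ beta_x
    ry = y - design @ beta_y
    # a variable that is an exact linear function of the covariates leaves only
    # round-off in its residuals; its partial correlation with anything is 0
    if np.std(rx) <= 1e-10 * max(np.std(x), 1e-300) or np.std(ry) <= 1e-10 * max(np.std(y), 1e-300):
        return {"r_partial": 0.0, "p": 1.0, "df": n - 2 - k}
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    t = r * np.sqrt(df / max(1e-300, 1.0 - r**2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return {"r_partial": r, "p": p, "df": df}


def compare_fisher(r1: float, n1: int, r2: float, n2: int) -> dict:
    """Fisher z-test for the difference of two independent correlations."""
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("correlations must satisfy |r| < 1")
    if n1 < 4 or n2 < 4:
        raise ValueError("need n >= 4 in both samples")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return {"z": float(z), "p": p}


def subject_rates(table: pd.DataFrame, parameter: str) -> pd.DataFrame:
    """Per-subject two-point rates of change (units/week) for longitudinal data.

    ``table`` needs columns ``subject``, ``ega_weeks`` and the parameter; each
    subject must have exactly two scans.
    """
    rows = []
    for subject, grp in table.groupby("subject"):
        if len(grp) != 2:
            continue
        grp = grp.sort_values("ega_weeks")
        dt = grp["ega_weeks"].iloc[1] - grp["ega_weeks"].iloc[0]
        dv = grp[parameter].iloc[1] - grp[parameter].iloc[0]
        rows.append({"subject": subject, "rate_per_week": dv / dt if dt > 0 else np.nan})
    return pd.DataFrame(rows)


def make_cohort_frame(records: list[dict]) -> pd.DataFrame:
    """Assemble and validate a tidy cohort table.

    One value per (subject, scan, region, parameter); scan EGA must be at
    least the EGA at birth.
    """
    df = pd.DataFrame(records)
    required = {"subject_id", "scan_id", "ega_birth", "ega_scan", "region", "parameter", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    if np.any(df["ega_scan"] < df["ega_birth"]):
        raise ValueError("ega_scan must be >= ega_birth")
    if df.duplicated(subset=["subject_id", "scan_id", "region", "parameter"]).any():
        raise ValueError("duplicate (subject, scan, region, parameter) entries")
    return df
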