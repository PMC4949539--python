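"""Published longitudinal regional estimates used as worked-example inputs.

Regional mean parameter values for the seven very-preterm infants with
usable two-time-point data, as printed in the source study's longitudinal
tables: the thalamus table carries the uncorrected intra-axonal fraction
v'_in, the myelin water fraction v_mwf, the printed myelin-corrected v_in,
bulk g-ratio and tissue T2; the posterior-white-matter (PWM) table carries
v'_in, v_mwf, corrected v_in and T2 for the spectroscopy-voxel region.
Parenthesized confidence half-widths accompany each printed mean.

Scans are labelled "early" (preterm scan, ~30-34 weeks EGA) and "late"
(term-equivalent scan).  The infant-4 late PWM row is absent in the source
(unusable spectroscopy data) and is omitted here.

These numbers are *inputs*: the package's fusion operations recompute the
corrected columns and the cohort myelin-attribution statistic from the
printed v'_in and v_mwf columns.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["thalamus_longitudinal", "pwm_longitudinal"]

_THALAMUS_ROWS = [
    # subject, scan, ega_weeks, v_in_prime, ci, v_mwf, ci, v_in_printed, ci, g_ratio_printed, ci, t2_ms, ci
    (1, "early", 33.14, 0.189, 0.0032, 0.0586, 0.0025, 0.178, 0.0030, 0.874, 0.0050, 203.0, 2.0),
    (1, "late", 40.14, 0.241, 0.0026, 0.1150, 0.0027, 0.213, 0.0024, 0.823, 0.0039, 177.0, 1.9),
    (2, "early", 31.43, 0.188, 0.0028, 0.0678, 0.0020, 0.175, 0.0026, 0.857, 0.0040, 197.0, 1.1),
    (2, "late", 42.00, 0.245, 0.0021, 0.1320, 0.0028, 0.213, 0.0019, 0.806, 0.0038, 175.0, 1.5),
    (3, "early", 31.00, 0.175, 0.0026, 0.0289, 0.0011, 0.170, 0.0025, 0.926, 0.0029, 204.0, 1.2),
    (3, "late", 42.00, 0.242, 0.0019, 0.1100, 0.0024, 0.215, 0.0018, 0.829, 0.0034, 172.0, 1.7),
    (4, "early", 30.86, 0.166, 0.0039, 0.0353, 0.0012, 0.160, 0.0037, 0.908, 0.0034, 208.0, 0.76),
    (4, "late", 46.29, 0.258, 0.0023, 0.1150, 0.0026, 0.228, 0.0021, 0.832, 0.0035, 178.0, 2.3),
    (5, "early", 29.86, 0.154, 0.0026, 0.0450, 0.0019, 0.147, 0.0025, 0.880, 0.0047, 215.0, 1.3),
    (5, "late", 46.29, 0.264, 0.0025, 0.1090, 0.0034, 0.235, 0.0024, 0.842, 0.0046, 186.0, 2.8),
    (6, "early", 31.86, 0.183, 0.0037, 0.0712, 0.0023, 0.170, 0.0034, 0.849, 0.0049, 194.0, 1.7),
    (6, "late", 40.29, 0.216, 0.0026, 0.0899, 0.0033, 0.197, 0.0025, 0.840, 0.0052, 192.0, 2.8),
    (7, "early", 34.57, 0.191, 0.0037, 0.0394, 0.0016, 0.183, 0.0035, 0.911, 0.0037, 200.0, 1.4),
    (7, "late", 40.29, 0.248, 0.0022, 0.0846, 0.0026, 0.227, 0.0021, 0.863, 0.0038, 185.0, 2.4),
]

_PWM_ROWS = [
    # subject, scan, ega_weeks, v_in_prime, ci, v_mwf, ci, v_in_printed, ci, t2_ms, ci
    (1, "early", 33.14, 0.083, 0.073, 0.0164, 0.004, 0.0817, 0.072, 283.0, 42.0),
    (1, "late", 40.14, 0.116, 0.073, 0.0221, 0.018, 0.1130, 0.072, 277.0, 42.0),
    (2, "early", 31.43, 0.115, 0.150, 0.0173, 0.005, 0.1130, 0.140, 292.0, 40.0),
    (2, "late", 42.00, 0.135, 0.052, 0.0177, 0.020, 0.1330, 0.051, 222.0, 27.0),
    (3, "early", 31.00, 0.095, 0.098, 0.0182, 0.008, 0.0935, 0.096, 290.0, 38.0),
    (3, "late", 42.00, 0.098, 0.053, 0.0376, 0.034, 0.0940, 0.051, 243.0, 35.0),
    (4, "early", 30.86, 0.087, 0.075, 0.0170, 0.006, 0.0854, 0.074, 305.0, 45.0),
    (5, "early", 29.86, 0.067, 0.065, 0.0165, 0.004, 0.0659, 0.063, 316.0, 49.0),
    (5, "late", 46.29, 0.166, 0.045, 0.0253, 0.026, 0.1620, 0.044, 209.0, 30.0),
    (6, "early", 31.86, 0.070, 0.087, 0.0169, 0.004, 0.0692, 0.085, 307.0, 36.0),
    (6, "late", 40.29, 0.090, 0.073, 0.0175, 0.007, 0.0887, 0.071, 242.0, 51.0),
    (7, "early", 34.57, 0.057, 0.060, 0.0176, 0.004, 0.0560, 0.059, 302.0, 43.0),
    (7, "late", 40.29, 0.095, 0.068, 0.0160, 0.008, 0.0933, 0.067, 240.0, 48.0),
]


def thalamus_longitudinal() -> pd.DataFrame:
    """Thalamic regional means for the seven longitudinal infants."""
    return pd.DataFrame(
        _THALAMUS_ROWS,
        columns=[
            "subject", "scan", "ega_weeks",
            "v_in_prime", "v_in_prime_ci", "v_mwf", "v_mwf_ci",
            "v_in_printed", "v_in_printed_ci", "g_ratio_printed", "g_ratio_printed_ci",
            "t2_ms", "t2_ci",
        ],
    )


def pwm_longitudinal() -> pd.DataFrame:
    """Posterior-white-matter regional means for the longitudinal infants."""
    return pd.DataFrame(
        _PWM_ROWS,
        columns=[
            "subject", "scan", "ega_weeks",
            "v_in_prime", "v_in_prime_ci", "v_mwf", "v_mwf_ci",
            "v_in_printed", "v_in_printed_ci", "t2_ms", "t2_ci",
        ],
    )
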