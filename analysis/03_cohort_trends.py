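"""Cohort trend analysis on synthetic developmental data.

Generates cohorts with the developmental rates reported for the preterm
period (thalamic tissue T2 falling at 2.24 ms/week, v_mwf rising at
0.48 %/week, PWM free water falling at 2.7 %/week), fits linear
parameter-vs-EGA trends, demonstrates EGA-adjusted partial correlation, and
compares regional rates with the Fisher z-test.

Writes results/cohort_trends.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from neomyelin.cohort import compare_fisher, linear_trend, partial_correlation
from neomyelin.synthetic import make_cohort

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

# (label, intercept at EGA 0, slope per week, noise sd, units)
TREND_SPECS = [
    ("thalamus_tissue_t2", 270.0, -2.24, 6.0, "ms"),
    ("thalamus_v_mwf_pct", -8.0, 0.48, 1.5, "%"),
    ("pwm_v_iso_pct", 120.0, -2.7, 8.0, "%"),
]


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--n-subjects", type=int, default=40)
    args = parser.parse_args()

    rows = []
    for i, (label, intercept, slope, sd, units) in enumerate(TREND_SPECS):
        cohort = make_cohort(args.n_subjects, intercept, slope, sd, seed=args.seed * 101 + i)
        res = linear_trend(cohort["value"].to_numpy(), cohort["ega_scan"].to_numpy())
        rows.append({"parameter": label, "true_slope": slope, "units_per_week": units, **res})
        print(
            f"{label}: fitted {res['slope']:+.3f} {units}/week (true {slope:+.2f}), "
            f"r = {res['r']:+.2f}, p = {res['p']:.2g}"
        )
    trends = pd.DataFrame(rows)
    trends.to_csv(OUT / "cohort_trends.csv", index=False)

    # two parameters driven by EGA correlate strongly raw; adjusting for EGA
    # removes the shared developmental trend
    rng = np.random.default_rng(args.seed)
    ega = rng.uniform(27, 58, 200)
    t2 = 270.0 - 2.24 * ega + rng.normal(0, 6, 200)
    naa_cho = -1.0 + 0.06 * ega + rng.normal(0, 0.15, 200)
    raw_r = float(np.corrcoef(t2, naa_cho)[0, 1])
    part = partial_correlation(t2, naa_cho, ega)
    print(
        f"T2 vs NAA/Cho: raw r = {raw_r:+.2f}; EGA-adjusted r = {part['r_partial']:+.2f} "
        f"(p = {part['p']:.2g}) — the raw association is carried by shared maturation"
    )

    # compare the two T2 rates via Fisher z on their correlations
    fast = linear_trend(t2, ega)
    slow_vals = 270.0 - 0.5 * ega + rng.normal(0, 6, 200)
    slow = linear_trend(slow_vals, ega)
    fz = compare_fisher(fast["r"], 200, slow["r"], 200)
    print(f"Fisher z comparing trend correlations ({fast['r']:+.2f} vs {slow['r']:+.2f}): z = {fz['z']:+.2f}, p = {fz['p']:.2g}")
    print(f"written: {OUT / 'cohort_trends.csv'}")


if __name__ == "__main__":
    main()
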