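"""Phantom round trip: generate, fit both modalities, fuse, compare to truth.

Renders the demo phantom (a thalamus-like block with a myelin-water gradient
and a PWM-like block with high free water), runs the full voxel-wise
relaxometry and diffusion fits, fuses them into four-compartment maps with
bulk g-ratio, and reports recovery errors against the generative truth,
noiseless and at realistic noise (Rician SNR 200 for the echo trains, 25
for DWI).

Writes results/phantom_recovery.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from neomyelin.diffusion import fit_dwi_volume
from neomyelin.fusion import fuse_maps
from neomyelin.relaxometry import fit_volume
from neomyelin.synthetic import default_phantom_spec, make_phantom

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)


def run_case(label, snr_t2, snr_dwi, seed):
    spec = default_phantom_spec(snr_t2=snr_t2, snr_dwi=snr_dwi, seed=seed)
    phantom = make_phantom(spec)
    t2_maps = fit_volume(phantom["echo"], phantom["mask"], spec.te_spacing)
    dwi_maps = fit_dwi_volume(phantom["dwi"], phantom["mask"], phantom["protocol"])
    fused = fuse_maps(t2_maps, dwi_maps, phantom["mask"])
    truth = phantom["truth"]

    rows = []
    for name in ("v_mwf", "v_in", "v_ex", "v_iso", "g_ratio"):
        err = np.abs(fused[name] - truth[name])
        rows.append(
            {
                "case": label,
                "parameter": name,
                "mean_abs_error": float(np.nanmean(err)),
                "median_abs_error": float(np.nanmedian(err)),
                "max_abs_error": float(np.nanmax(err)),
                "n_voxels": int(np.isfinite(err).sum()),
            }
        )
    return pd.DataFrame(rows)


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    results = pd.concat(
        [
            run_case("noiseless", np.inf, np.inf, args.seed),
            run_case("snr200_t2_snr25_dwi", 200.0, 25.0, args.seed),
        ]
    )
    results.to_csv(OUT / "phantom_recovery.csv", index=False)
    print(results.to_string(index=False))
    noiseless_g = results[(results["case"] == "noiseless") & (results["parameter"] == "g_ratio")]
    print(
        f"\nnoiseless bulk g-ratio recovered to {noiseless_g['max_abs_error'].iloc[0]:.4f} "
        f"(worst voxel); written to {OUT / 'phantom_recovery.csv'}"
    )


if __name__ == "__main__":
    main()
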