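"""Least-squares ACF fitting bias in photon-poor conditions.

Simulates a photon-starved variant of the iFCS scenario (3 photons per
molecule per frame) and tests whether fitted relaxation times fall
systematically below the simulated ground truth (one-sided sign test) —
the known bias of weighted-least-squares autocorrelation fitting in dim
regions. Results: results/estimator_bias.csv.
"""

from pathlib import Path

import pandas as pd
from scipy import stats

from tabsr import ifcs, simulate

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SEED = 3


def main() -> None:
    acq = simulate.ifcs_acquisition(n_frames=18_000, fov_px=(32, 32))
    kin = simulate.default_kinetics()
    optics = simulate.default_optics(
        acq, mean_photons_per_frame=3.0, background_photons_per_pixel_per_frame=0.05
    )
    movie, _ = simulate.simulate_scenario(acq, kinetics=kin, optics=optics, seed=SEED)
    stack = ifcs.segmented_acf(movie, n_segments=6)
    fits = ifcs.fit_all_pixels(stack, snr_gate=3.0)
    good = fits[fits.converged]

    rows = []
    for name, true_tau, col in (
        ("tau_fast", kin.tau_fast_ms, good.tau_fast_ms),
        ("tau_slow", kin.tau_slow_ms, good.tau_slow_ms),
    ):
        n_below = int((col < true_tau).sum())
        p = stats.binomtest(n_below, len(good), alternative="greater").pvalue
        rows.append({
            "parameter": name, "true_ms": true_tau, "median_fit_ms": col.median(),
            "n_pixels": len(good), "n_below_truth": n_below, "sign_test_p": p,
        })
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "estimator_bias.csv", index=False)
    print(df.to_string(index=False))
    print("\nboth relaxation times are systematically underestimated"
          if (df.sign_test_p < 0.05).all()
          else "\nno significant bias detected")


if __name__ == "__main__":
    main()
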