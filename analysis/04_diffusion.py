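#!/usr/bin/env python
"""Estimate a lateral diffusion coefficient from Brownian walks simulated at
D = 0.3 A^2/ns (3.0e-8 cm^2/s, the single-particle-tracking value for the
membrane-bound PH domain) via the all-origin 2D MSD and the Einstein
relation.  Writes results/msd.tsv and results/diffusion_estimate.json."""

import json
from pathlib import Path

from memprobe.diffusion import compute_msd_2d, fit_einstein_2d
from memprobe.synth import simulate_brownian_2d

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 1) -> None:
    pos, truth = simulate_brownian_2d(D=0.3, dt=0.01, n_steps=10_000,
                                      n_walkers=100, seed=seed)
    msd = compute_msd_2d(pos, dt=0.01)
    est = fit_einstein_2d(msd, positions=pos, dt=0.01)

    RESULTS.mkdir(exist_ok=True)
    with open(RESULTS / "msd.tsv", "w") as fh:
        fh.write("lag_ns\tmsd_A2\tn_origins\n")
        for lag, m, n in zip(msd.lag[::50], msd.msd[::50], msd.n_origins[::50]):
            fh.write(f"{lag:.4g}\t{m:.6g}\t{n}\n")
    out = dict(D_cm2_per_s=est.D, D_err_cm2_per_s=est.D_err,
               slope_A2_per_ns=est.slope, r_squared=est.r_squared,
               fit_window_ns=est.fit_window, method=est.method,
               D_true_cm2_per_s=truth["D_cm2_per_s"])
    (RESULTS / "diffusion_estimate.json").write_text(
        json.dumps(out, indent=2) + "\n")
    print(f"D = {est.D:.3e} +/- {est.D_err:.1e} cm^2/s "
          f"(truth {truth['D_cm2_per_s']:.1e}; fit r^2 = {est.r_squared:.4f})")


if __name__ == "__main__":
    main()
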