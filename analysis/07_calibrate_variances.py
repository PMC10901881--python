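#!/usr/bin/env python
"""Calibrate the generator's variance components to the reported
explanatory-power regime.

The fixed effects imply a fixed-effect variance of ~1,085 ms^2 over the
balanced design.  For the fitted model to show marginal R^2 ~ 0.09 and
conditional R^2 ~ 0.90, the random-effect variance must be ~9x and the
residual ~1.1x the fixed variance.  This driver sweeps the random
intercept SD around the analytic solution and reports fitted R^2 on
freshly simulated studies, confirming the shipped defaults.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from tacstrial import cohort, lmm, preprocess
from tacstrial.cohort import GenerativeModel

OUT = Path("results")


def fit_r2(model: GenerativeModel, seed: int) -> tuple[float, float]:
    profiles = cohort.sample_cohort(model=model, rng_seed=seed)
    trials = cohort.simulate_responses(profiles, model, rng_seed=seed + 1000)
    filtered, _ = preprocess.filter_trials(trials)
    agg = preprocess.aggregate_epochs(filtered)
    fit = lmm.fit_model(agg, lmm.SELECTED_MODEL, standardize=False)
    return fit.marginal_r2, fit.conditional_r2


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows = []
    for sd_int in (70.0, 96.0, 120.0):
        model = GenerativeModel(sd_intercept=sd_int)
        r2 = [fit_r2(model, seed) for seed in range(4)]
        marg = float(np.mean([m for m, _ in r2]))
        cond = float(np.mean([c for _, c in r2]))
        rows.append({"sd_intercept": sd_int, "marginal_r2": marg,
                     "conditional_r2": cond})
        print(
            f"sd_intercept={sd_int:6.1f}  marginal R2={marg:.3f}  "
            f"conditional R2={cond:.3f}"
        )
    pd.DataFrame(rows).to_csv(OUT / "variance_calibration.csv", index=False)
    print(
        "\nshipped default: sd_intercept=96 ms (conditional R2 near 0.90, "
        "marginal R2 in the 0.05-0.15 band; single-study values vary with "
        "the realized group imbalance at n=35)"
    )


if __name__ == "__main__":
    main()
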