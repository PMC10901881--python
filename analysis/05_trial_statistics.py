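#!/usr/bin/env python
"""Trial-level auxiliary statistics on the simulated study.

Baseline comparability of the two groups (t-tests, chi-squared for the
gender split), adverse-event comparisons per category (unpaired t-tests
on per-session counts) and the blinding assessment (correct-guess
proportion, chi-squared, Fisher exact on the 2x3 table).
"""

from pathlib import Path

import pandas as pd

from tacstrial import trialstats
from tacstrial.pipeline import dump_json

OUT = Path("results/study")


def main() -> None:
    profiles = pd.read_csv(OUT / "participants.csv")
    guesses = pd.read_csv(OUT / "blinding_guesses.csv")
    ae_counts = pd.read_csv(OUT / "adverse_events.csv")

    blinding = trialstats.blinding_assessment(trialstats.blinding_table(guesses))
    baseline = trialstats.baseline_comparisons(profiles)
    ae_tests = trialstats.adverse_event_comparison(ae_counts)

    dump_json(
        {
            "blinding": blinding.to_dict(),
            "baseline": [t.__dict__ for t in baseline],
            "adverse_events": [t.__dict__ for t in ae_tests],
        },
        OUT / "trial_statistics.json",
    )
    (OUT / "baseline_table.txt").write_text(
        trialstats.baseline_table(profiles) + "\n"
    )

    print(trialstats.baseline_table(profiles))
    print(
        f"\nblinding: {blinding.correct_proportion:.0%} guessed right; "
        f"chi2 = {blinding.chi2:.2f} (p = {blinding.chi2_p:.2f}), "
        f"Fisher exact p = {blinding.fisher_p:.2f}"
    )
    print("\nadverse events (per-session t-tests):")
    for t in ae_tests:
        print(f"  {t.variable:<16} p = {t.p:.2f}  {t.note}")


if __name__ == "__main__":
    main()
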