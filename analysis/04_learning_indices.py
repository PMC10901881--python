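#!/usr/bin/env python
"""Translate the selected model into the four learning indices.

Online sequence-specific learning (lpt - hpt), online visuomotor
learning (epoch slope), offline visuomotor learning (session contrasts
per group) and the group offline gain (group x session), plus the
model-free descriptive change scores and the two-panel learning figure.
"""

from pathlib import Path

import pandas as pd

from tacstrial import lmm, outcomes
from tacstrial.pipeline import dump_json

OUT = Path("results/study")


def main() -> None:
    aggregates = pd.read_csv(OUT / "epoch_aggregates.csv")
    fit = lmm.fit_model(aggregates, lmm.SELECTED_MODEL, standardize=False)
    indices = outcomes.extract_indices(fit)
    scores = outcomes.descriptive_scores(aggregates)

    dump_json(indices.to_dict(), OUT / "learning_indices.json")
    scores.per_participant.to_csv(OUT / "learning_scores.csv", index=False)
    outcomes.plot_learning(scores, aggregates, str(OUT / "learning.png"))

    def show(label, c):
        if c is None:
            print(f"{label}: not in model")
        else:
            print(f"{label}: {c.estimate:+.2f} ms [{c.ci_low:.2f}, {c.ci_high:.2f}]")

    show("online sequence-specific (lpt - hpt)", indices.online_sequence_specific)
    show("online visuomotor (per epoch)", indices.online_visuomotor)
    for k, c in indices.offline_visuomotor.items():
        show(f"offline visuomotor {k}", c)
    for k, c in indices.group_offline_gain.items():
        show(f"group offline gain {k}", c)
    if scores.excluded_participants:
        print("excluded from descriptive scores:", scores.excluded_participants)


if __name__ == "__main__":
    main()
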