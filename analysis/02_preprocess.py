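#!/usr/bin/env python
"""Apply the exclusion cascade and build the epoch-level modelling table.

Removes practice blocks, the first two stimuli of every test block, and
all trills/repetitions (about 22% of original trials), then aggregates
median RT of correct responses and mean accuracy per participant x
session x epoch x trial type (840 rows for the default design).
"""

from pathlib import Path

from tacstrial import preprocess
from tacstrial.pipeline import dump_json, read_trials

OUT = Path("results/study")


def main() -> None:
    trials = read_trials(OUT / "trials.csv")
    filtered, report = preprocess.filter_trials(trials)
    aggregates = preprocess.aggregate_epochs(filtered)

    aggregates.to_csv(OUT / "epoch_aggregates.csv", index=False)
    dump_json(report.to_dict(), OUT / "exclusion_report.json")

    r = report
    print(
        f"excluded {r.n_removed} of {r.n_original} trials "
        f"({100 * r.excluded_fraction:.1f}%): "
        f"{r.removed_practice} practice, {r.removed_first_two} first-two, "
        f"{r.removed_trill} trills, {r.removed_repetition} repetitions"
    )
    print(f"modelling table: {len(aggregates)} rows")
    if aggregates.attrs.get("empty_cells"):
        print(f"warning: {len(aggregates.attrs['empty_cells'])} empty cells")


if __name__ == "__main__":
    main()
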