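"""Trial exclusion and epoch-level aggregation.

Before modelling, each session's trials pass through the standard ASRT
exclusion cascade, applied in order with each trial attributed to the
first rule that removes it:

1. practice blocks (160 trials per session under the default design),
2. the first two stimuli of every test block (40 per session),
3. trills (x-y-x) and repetitions (x-x-x), flagged on the raw stream.

Together these remove about 22% of the original trials.  Incorrect
responses are *not* removed: they are excluded only from the RT median,
while accuracy averages over all retained trials ("median of correct
responses and mean of all responses").

Retained trials are aggregated per participant x session x epoch (five
consecutive test blocks) x trial type into the epoch-level modelling
table: 35 participants x 3 sessions x 4 epochs x 2 trial types = 840 rows
under the default design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = [
    "participant_id",
    "session",
    "block",
    "trial_index_in_block",
    "is_practice",
    "triplet_class",
    "is_trill",
    "is_repetition",
    "rt_ms",
    "correct",
]

BLOCKS_PER_EPOCH = 5


@dataclass
class ExclusionReport:
    """Accounting of the exclusion cascade."""

    n_original: int
    removed_practice: int
    removed_first_two: int
    removed_trill: int
    removed_repetition: int
    extra: dict = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return (
            self.removed_practice
            + self.removed_first_two
            + self.removed_trill
            + self.removed_repetition
        )

    @property
    def n_retained(self) -> int:
        return self.n_original - self.n_removed

    @property
    def excluded_fraction(self) -> float:
        return self.n_removed / self.n_original if self.n_original else 0.0

    def to_dict(self) -> dict:
        return {
            "n_original": self.n_original,
            "removed_practice": self.removed_practice,
            "removed_first_two": self.removed_first_two,
            "removed_trill": self.removed_trill,
            "removed_repetition": self.removed_repetition,
            "n_removed": self.n_removed,
            "n_retained": self.n_retained,
            "excluded_fraction": self.excluded_fraction,
            **self.extra,
        }


def filter_trials(trials: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the exclusion cascade; return retained trials and the report.

    Incorrect-response trials are kept (the RT median later ignores
    them).  Raises if annotation columns are missing.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table lacks required columns: {missing}")

    practice = trials["is_practice"].to_numpy(dtype=bool)
    first_two = (~practice) & (trials["trial_index_in_block"].to_numpy() <= 2)
    trill = (~practice) & (~first_two) & trials["is_trill"].to_numpy(dtype=bool)
    rep = (
        (~practice)
        & (~first_two)
        & (~trill)
        & trials["is_repetition"].to_numpy(dtype=bool)
    )
    removed = practice | first_two | trill | rep

    report = ExclusionReport(
        n_original=len(trials),
        removed_practice=int(practice.sum()),
        removed_first_two=int(first_two.sum()),
        removed_trill=int(trill.sum()),
        removed_repetition=int(rep.sum()),
    )
    return trials.loc[~removed].copy(), report


def aggregate_epochs(
    filtered: pd.DataFrame,
    *,
    practice_blocks: int = 2,
    blocks_per_epoch: int = BLOCKS_PER_EPOCH,
) -> pd.DataFrame:
    """Collapse retained trials to the epoch-level modelling table.

    Epoch e covers test blocks 5(e-1)+1 .. 5e.  ``median_rt_ms`` is the
    median RT of correct responses; ``mean_accuracy`` the mean
    correctness over all retained trials of the cell.  Cells with zero
    correct trials keep a missing median and are flagged in the output
    attribute ``empty_cells``.
    """
    df = filtered.copy()
    test_block = df["block"].to_numpy() - practice_blocks
    if np.any(test_block < 1):
        raise ValueError("filtered table still contains practice blocks")
    df["epoch"] = (test_block - 1) // blocks_per_epoch + 1
    df["trial_type"] = np.where(df["triplet_class"] == "high", "hpt", "lpt")

    keys = ["participant_id", "session", "epoch", "trial_type"]
    if "group" in df.columns:
        keys.insert(1, "group")

    correct = df["correct"].astype("boolean")
    df["_rt_correct"] = df["rt_ms"].where(correct.fillna(False).to_numpy())
    df["_acc"] = correct.astype("Float64")

    agg = (
        df.groupby(keys, observed=True)
        .agg(
            median_rt_ms=("_rt_correct", "median"),
            mean_accuracy=("_acc", "mean"),
            n_trials=("rt_ms", "size"),
        )
        .reset_index()
    )
    agg["mean_accuracy"] = agg["mean_accuracy"].astype(float)
    empty = agg[agg["median_rt_ms"].isna()]
    agg.attrs["empty_cells"] = empty[
        ["participant_id", "session", "epoch", "trial_type"]
    ].to_dict("records")
    return agg


def expected_excluded_fraction(
    *,
    n_blocks: int = 20,
    trials_per_block: int = 80,
    practice_blocks: int = 2,
) -> float:
    """Analytic expectation of the excluded fraction for one session.

    Practice and first-two removals are deterministic.  Among the
    remaining trials, only random-ending (even-index) triplets can be
    trills or repetitions, each with combined probability 1/4 under a
    uniform random element (3/16 trill + 1/16 repetition).
    """
    n_original = (n_blocks + practice_blocks) * trials_per_block
    removed = practice_blocks * trials_per_block + 2 * n_blocks
    # even trial indices 4, 6, ..., trials_per_block within each block
    n_random_classifiable = n_blocks * (trials_per_block // 2 - 1)
    removed += 0.25 * n_random_classifiable
    return removed / n_original
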