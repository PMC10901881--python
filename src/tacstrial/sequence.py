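"""Alternating serial reaction time (ASRT) stimulus streams.

The ASRT task presents a stimulus in one of four horizontal screen
positions (numbered 1-4, left to right).  The stream alternates fixed
*pattern* elements, drawn cyclically from a hidden 4-element pattern,
with uniformly *random* elements: P r P r P r P r ...  Because of this
structure, some runs of three consecutive stimuli ("triplets") are much
more frequent than others.  A triplet whose first-to-third transition
matches a pattern transition is *high probability* (62.5% of
classifiable trials); all others are *low probability* (37.5%).

Every trial is scored as the terminal element of its triplet, using the
raw stimulus stream, never the filtered data.  Triplets of the form
x-y-x ("trills") and x-x-x ("repetitions") receive structural flags so
the preprocessing stage can exclude them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

N_POSITIONS = 4

#: Canonical column order of a trial table (the tidy trial CSV schema).
TRIAL_COLUMNS = [
    "participant_id",
    "session",
    "block",
    "trial_index_in_block",
    "stimulus_position",
    "trial_type",
    "is_practice",
    "triplet_class",
    "is_trill",
    "is_repetition",
    "rt_ms",
    "correct",
]


@dataclass(frozen=True)
class PatternSequence:
    """Hidden 4-element pattern defining the alternating sequence.

    ``positions`` is a permutation of (1, 2, 3, 4); pattern element i is
    followed, cyclically, by element i+1.  A pattern (3, 2, 4, 1) yields
    the eight-element sequence 3-r-2-r-4-r-1-r.
    """

    positions: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if sorted(self.positions) != [1, 2, 3, 4]:
            raise ValueError(
                f"pattern must be a permutation of 1..4, got {self.positions}"
            )

    def successor(self, position: int) -> int:
        """Cyclic pattern successor of ``position``."""
        i = self.positions.index(position)
        return self.positions[(i + 1) % 4]

    @property
    def transitions(self) -> set[tuple[int, int]]:
        """The four (first, third) transitions that make a triplet high."""
        return {(p, self.successor(p)) for p in self.positions}


@dataclass(frozen=True)
class TripletClass:
    """Classification of one triplet of consecutive stimuli."""

    high: bool
    trill: bool
    repetition: bool

    @property
    def label(self) -> str:
        return "high" if self.high else "low"


def generate_pattern(rng_seed: int) -> PatternSequence:
    """Draw a pattern uniformly from the 24 permutations of 1..4."""
    rng = np.random.default_rng(rng_seed)
    return PatternSequence(tuple(rng.permutation([1, 2, 3, 4]).tolist()))


def all_patterns() -> list[PatternSequence]:
    """Every valid pattern (useful for exhaustive checks)."""
    return [PatternSequence(p) for p in itertools.permutations((1, 2, 3, 4))]


def classify_triplet(
    e1: int, e2: int, e3: int, pattern: PatternSequence
) -> TripletClass:
    """Classify the triplet (e1, e2, e3) under ``pattern``.

    High iff e3 is the cyclic pattern successor of e1.  Trill iff
    e1 == e3 != e2; repetition iff e1 == e2 == e3.  Flags are computed
    from the raw positions only.
    """
    for e in (e1, e2, e3):
        if e not in (1, 2, 3, 4):
            raise ValueError(f"positions must be in 1..4, got {(e1, e2, e3)}")
    high = pattern.successor(e1) == e3
    repetition = e1 == e2 == e3
    trill = (e1 == e3) and (e1 != e2)
    return TripletClass(high=high, trill=trill, repetition=repetition)


def triplet_probability(pattern: PatternSequence, which: str = "high") -> float:
    """Analytic probability that a classifiable trial ends a high (or low)
    probability triplet.

    Classifiable trials (index >= 3 of a test block) split evenly between
    the two parities: pattern-ending triplets are P-r-P and always follow
    a pattern transition; random-ending triplets are r-P-r and match a
    pattern transition only when the uniform random element happens to hit
    the successor (probability 1/4).
    """
    if which not in ("high", "low"):
        raise ValueError("which must be 'high' or 'low'")
    # average over equally frequent parities; independent of the pattern
    _ = pattern.transitions  # validates the pattern
    p_high = 0.5 * 1.0 + 0.5 * (1.0 / N_POSITIONS)
    return p_high if which == "high" else 1.0 - p_high


def generate_session(
    pattern: PatternSequence,
    *,
    participant_id: str | int = "P01",
    session: int = 1,
    n_blocks: int = 20,
    trials_per_block: int = 80,
    practice_blocks: int = 2,
    rng_seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Generate the stimulus stream of one ASRT session (no responses).

    A session is ``practice_blocks`` blocks of uniform-random stimuli
    followed by ``n_blocks`` test blocks of ``trials_per_block`` trials
    each.  Test blocks alternate pattern and random elements starting with
    a pattern element; the pattern phase runs on seamlessly across blocks.
    Triplet annotations are filled for trial index >= 3 within each block;
    the first two trials of every block are 'undefined'.

    Returns a tidy trial table (one row per stimulus) with ``rt_ms`` and
    ``correct`` left missing.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if trials_per_block % 8 != 0:
        raise ValueError(
            f"trials_per_block must be a multiple of 8, got {trials_per_block}"
        )
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )

    frames = []
    for b in range(1, practice_blocks + 1):
        positions = rng.integers(1, N_POSITIONS + 1, size=trials_per_block)
        frames.append(
            _block_frame(
                positions,
                block=b,
                is_practice=True,
                trial_type=np.full(trials_per_block, "random"),
                pattern=pattern,
            )
        )

    n_test_trials = n_blocks * trials_per_block
    positions = np.empty(n_test_trials, dtype=np.int64)
    n_pattern = n_test_trials // 2
    pat = np.asarray(pattern.positions)
    positions[0::2] = np.resize(pat, n_pattern)  # phase continues across blocks
    positions[1::2] = rng.integers(1, N_POSITIONS + 1, size=n_test_trials - n_pattern)
    trial_type = np.where(np.arange(n_test_trials) % 2 == 0, "pattern", "random")

    for b in range(n_blocks):
        sl = slice(b * trials_per_block, (b + 1) * trials_per_block)
        frames.append(
            _block_frame(
                positions[sl],
                block=practice_blocks + b + 1,
                is_practice=False,
                trial_type=trial_type[sl],
                pattern=pattern,
            )
        )

    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "participant_id", str(participant_id))
    out.insert(1, "session", session)
    out["rt_ms"] = np.nan
    out["correct"] = pd.array([pd.NA] * len(out), dtype="boolean")
    return out[TRIAL_COLUMNS]


def _block_frame(
    positions: np.ndarray,
    *,
    block: int,
    is_practice: bool,
    trial_type: np.ndarray,
    pattern: PatternSequence,
) -> pd.DataFrame:
    """Assemble one block's rows with within-block triplet annotations."""
    n = len(positions)
    succ = np.zeros(N_POSITIONS + 1, dtype=np.int64)
    for p in range(1, N_POSITIONS + 1):
        succ[p] = pattern.successor(p)

    triplet_class = np.full(n, "undefined", dtype=object)
    is_trill = np.zeros(n, dtype=bool)
    is_rep = np.zeros(n, dtype=bool)
    if n >= 3:
        e1, e2, e3 = positions[:-2], positions[1:-1], positions[2:]
        high = succ[e1] == e3
        triplet_class[2:] = np.where(high, "high", "low")
        is_trill[2:] = (e1 == e3) & (e1 != e2)
        is_rep[2:] = (e1 == e2) & (e2 == e3)

    return pd.DataFrame(
        {
            "block": block,
            "trial_index_in_block": np.arange(1, n + 1),
            "stimulus_position": positions,
            "trial_type": trial_type,
            "is_practice": is_practice,
            "triplet_class": triplet_class,
            "is_trill": is_trill,
            "is_repetition": is_rep,
        }
    )
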