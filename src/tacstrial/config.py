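"""Study configuration: everything that determines a simulated run.

A ``StudyConfig`` pins cohort sizes, the session/block/trial layout, the
generative-model coefficients and variances, per-stage seeds and output
paths, and serializes to/from YAML so a simulated study is
bit-reproducible from its config file alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .cohort import STUDY_FIXED_EFFECTS, GenerativeModel


@dataclass
class StudyConfig:
    n_active: int = 17
    n_sham: int = 18
    sessions: int = 3
    n_blocks: int = 20
    trials_per_block: int = 80
    practice_blocks: int = 2
    same_pattern_across_sessions: bool = True

    fixed_effects: dict = field(default_factory=lambda: dict(STUDY_FIXED_EFFECTS))
    sd_intercept: float = 96.0
    sd_epoch_slope: float = 8.0
    re_correlation: float = 0.0
    cell_sd: float = 33.0
    trial_lognorm_sigma: float = 0.20
    accuracy_base: float = 0.97

    guess_probs: tuple = (0.5, 0.4, 0.1)
    n_stim_sessions: int = 16

    seed_cohort: int = 11
    seed_responses: int = 22
    seed_meta: int = 33

    out_dir: str = "results/study"

    def __post_init__(self) -> None:
        if self.n_active < 1 or self.n_sham < 1:
            raise ValueError("both groups need at least one participant")
        if self.sessions < 1:
            raise ValueError("need at least one session")
        if self.trials_per_block % 8 != 0:
            raise ValueError("trials_per_block must be a multiple of 8")

    @property
    def generative_model(self) -> GenerativeModel:
        return GenerativeModel(
            fixed_effects=dict(self.fixed_effects),
            sd_intercept=self.sd_intercept,
            sd_epoch_slope=self.sd_epoch_slope,
            re_correlation=self.re_correlation,
            cell_sd=self.cell_sd,
            trial_lognorm_sigma=self.trial_lognorm_sigma,
            accuracy_base=self.accuracy_base,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "guess_probs" in data:
            data["guess_probs"] = tuple(data["guess_probs"])
        return cls(**data)

    def digest(self) -> str:
        """Stable hash embedded in every report for provenance.

        Output paths are excluded: where a run writes does not change
        what it computes.
        """
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
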