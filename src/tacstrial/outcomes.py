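"""Learning indices derived from the fitted model and from raw aggregates.

The trial distinguishes four facets of implicit learning, each a linear
combination of fixed-effect coefficients of the selected model:

* online sequence-specific learning — the trial-type contrast (lpt - hpt
  RT, ms); positive values mean faster responses to high-probability
  triplets, i.e. sequence knowledge.
* offline sequence-specific learning — trial_type x session contrasts
  (null when the selected model omits them, which is the study's
  finding).
* online visuomotor learning — the epoch slope (ms/epoch); negative
  values mean speed-up within a session.
* offline visuomotor learning — session contrasts (session 2 - 1 and
  3 - 1, ms) for the reference (sham) group and for the active group
  (session + group x session), negative = faster across sessions.
* group offline gain — the group x session interaction itself: how much
  more the active group improves across sessions than sham.

Confidence intervals for compound contrasts use the delta method on the
fixed-effect covariance.  Descriptive, model-free per-participant scores
(baseline-to-post and baseline-to-follow-up RT change, per-session
lpt - hpt difference) complement the model-based indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps

from .lmm import ModelFit


@dataclass(frozen=True)
class Contrast:
    """A linear combination of coefficients with a delta-method CI."""

    name: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float


@dataclass
class LearningIndices:
    online_sequence_specific: Contrast | None
    offline_sequence_specific: dict[str, Contrast]
    online_visuomotor: Contrast | None
    offline_visuomotor: dict[str, Contrast]
    group_offline_gain: dict[str, Contrast]

    def to_dict(self) -> dict:
        def c2d(c):
            return None if c is None else c.__dict__

        return {
            "online_sequence_specific": c2d(self.online_sequence_specific),
            "offline_sequence_specific": {
                k: c2d(v) for k, v in self.offline_sequence_specific.items()
            },
            "online_visuomotor": c2d(self.online_visuomotor),
            "offline_visuomotor": {
                k: c2d(v) for k, v in self.offline_visuomotor.items()
            },
            "group_offline_gain": {
                k: c2d(v) for k, v in self.group_offline_gain.items()
            },
        }


def _contrast(fit: ModelFit, name: str, weights: dict[str, float]) -> Contrast | None:
    """Delta-method contrast over named coefficients; None if terms absent."""
    missing = [k for k in weights if k not in fit.coefficients]
    if missing:
        return None
    est = sum(w * fit.coefficients[k].beta for k, w in weights.items())
    if fit.fe_cov is not None and all(k in fit.fe_cov.index for k in weights):
        names = list(weights)
        w = np.array([weights[k] for k in names])
        V = fit.fe_cov.loc[names, names].to_numpy()
        se = float(np.sqrt(w @ V @ w))
    else:  # fall back to independent-coefficient approximation
        se = float(
            np.sqrt(sum((w * fit.coefficients[k].se) ** 2 for k, w in weights.items()))
        )
    df = next(iter(fit.coefficients.values())).df
    tcrit = sps.t.ppf(0.975, df)
    return Contrast(name, float(est), se, float(est - tcrit * se), float(est + tcrit * se))


def extract_indices(fit: ModelFit) -> LearningIndices:
    """Map the selected model's coefficients to the four learning indices.

    Offline contrasts are session main-effect/interaction contrasts at
    the reference coding (sham, hpt); absent terms yield explicit nulls.
    """
    if "intercept" not in fit.coefficients:
        raise ValueError("fit uses an unexpected coding: no intercept term")
    offline_vm: dict[str, Contrast] = {}
    gain: dict[str, Contrast] = {}
    offline_seq: dict[str, Contrast] = {}
    for s in (2, 3):
        c = _contrast(fit, f"sham_session{s}_minus_1", {f"session{s}": 1.0})
        if c:
            offline_vm[f"sham_session{s}"] = c
        c = _contrast(
            fit,
            f"active_session{s}_minus_1",
            {f"session{s}": 1.0, f"group_active:session{s}": 1.0},
        )
        if c:
            offline_vm[f"active_session{s}"] = c
        c = _contrast(
            fit, f"group_gain_session{s}", {f"group_active:session{s}": 1.0}
        )
        if c:
            gain[f"session{s}"] = c
        c = _contrast(
            fit, f"trial_type_x_session{s}", {f"trial_type_lpt:session{s}": 1.0}
        )
        if c:
            offline_seq[f"session{s}"] = c

    return LearningIndices(
        online_sequence_specific=_contrast(
            fit, "lpt_minus_hpt", {"trial_type_lpt": 1.0}
        ),
        offline_sequence_specific=offline_seq,
        online_visuomotor=_contrast(fit, "epoch_slope", {"epoch": 1.0}),
        offline_visuomotor=offline_vm,
        group_offline_gain=gain,
    )


@dataclass
class DescriptiveLearningScores:
    """Model-free per-participant learning scores."""

    per_participant: pd.DataFrame  # change_post, change_followup, seq per session
    group_summary: pd.DataFrame  # mean and SEM per group
    excluded_participants: list[str]


def descriptive_scores(aggregates: pd.DataFrame) -> DescriptiveLearningScores:
    """Within-participant session-mean RT changes and lpt-hpt differences.

    change_post = session-2 mean - session-1 mean (baseline to
    post-treatment); change_followup = session-3 mean - session-1 mean.
    Participants missing any of the three sessions are excluded from
    group summaries and listed in ``excluded_participants``.
    """
    sess_mean = (
        aggregates.groupby(["participant_id", "group", "session"], observed=True)[
            "median_rt_ms"
        ]
        .mean()
        .unstack("session")
    )
    seq = (
        aggregates.pivot_table(
            index=["participant_id", "session"],
            columns="trial_type",
            values="median_rt_ms",
            aggfunc="mean",
            observed=True,
        )
        .assign(seq_learning=lambda d: d.get("lpt") - d.get("hpt"))["seq_learning"]
        .unstack("session")
        .add_prefix("seq_learning_s")
    )

    complete = sess_mean.dropna(subset=[1, 2, 3]).copy() if set(
        [1, 2, 3]
    ) <= set(sess_mean.columns) else sess_mean.iloc[0:0].copy()
    excluded = sorted(
        set(sess_mean.index.get_level_values(0))
        - set(complete.index.get_level_values(0))
    )
    per = complete.rename(columns=lambda s: f"session{s}_mean").reset_index()
    for s in (1, 2, 3):  # keep schema stable even when a session is absent
        per[f"session{s}_mean"] = per.get(f"session{s}_mean", np.nan)
    per["change_post"] = per["session2_mean"] - per["session1_mean"]
    per["change_followup"] = per["session3_mean"] - per["session1_mean"]
    per = per.merge(seq.reset_index(), on="participant_id", how="left")

    summary = (
        per.groupby("group")[["change_post", "change_followup"]]
        .agg(["mean", "sem", "count"])
        .round(6)
    )
    return DescriptiveLearningScores(
        per_participant=per, group_summary=summary, excluded_participants=excluded
    )


def plot_learning(
    scores: DescriptiveLearningScores, aggregates: pd.DataFrame, path: str
) -> None:
    """Two-panel figure: session-mean RT lines per group; change-score
    bars with SEM."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    sess = (
        aggregates.groupby(["group", "session"], observed=True)["median_rt_ms"]
        .agg(["mean", "sem"])
        .reset_index()
    )
    for group, color in (("active", "tab:blue"), ("sham", "tab:orange")):
        d = sess[sess["group"] == group]
        ax1.errorbar(
            d["session"], d["mean"], yerr=d["sem"], label=group, color=color,
            marker="o",
        )
    ax1.set_xlabel("session")
    ax1.set_ylabel("median RT (ms)")
    ax1.set_xticks([1, 2, 3])
    ax1.legend()

    gs = scores.group_summary
    x = np.arange(2)
    for i, group in enumerate(gs.index):
        means = [gs.loc[group, ("change_post", "mean")],
                 gs.loc[group, ("change_followup", "mean")]]
        sems = [gs.loc[group, ("change_post", "sem")],
                gs.loc[group, ("change_followup", "sem")]]
        ax2.bar(x + 0.35 * i, means, 0.35, yerr=sems, label=group)
    ax2.set_xticks(x + 0.175)
    ax2.set_xticklabels(["baseline→post", "baseline→follow-up"])
    ax2.set_ylabel("RT change (ms)")
    ax2.axhline(0, color="k", lw=0.5)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
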