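"""Auxiliary randomized-trial statistics: blinding, baseline, adverse events.

Blinding is assessed on the 2x3 contingency table of true group (active,
sham) against the participant's end-of-study guess (Active, Sham,
I don't know): the correct-guess proportion, Pearson's chi-squared test
of independence, and — because "I don't know" cells are small — the
Fisher exact test.  For 2x3 tables the exact test is the
Freeman-Halton extension computed by full enumeration of tables with
the observed margins (counts here are tiny, so enumeration is exact and
fast); 2x2 sub-tables use the same machinery and agree with the
hypergeometric formula.

Baseline comparability uses two-sample two-sided t-tests for age,
education and MoCA and a chi-squared test for the gender split.
Adverse-event counts are compared per category with unpaired two-sided
t-tests over per-session counts.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps

GUESS_LEVELS = ["Active", "Sham", "I don't know"]
AE_CATEGORIES = ["tingling", "skin_irritation", "headache", "tiredness", "phosphenes"]


def chi_squared_statistic(table: np.ndarray) -> tuple[float, int]:
    """Pearson chi-squared statistic and df, sum (O-E)^2/E, no correction."""
    table = np.asarray(table, dtype=float)
    if table.sum() == 0:
        raise ValueError("all-zero contingency table")
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    expected = rows @ cols / table.sum()
    mask = expected > 0
    stat = float(((table - expected)[mask] ** 2 / expected[mask]).sum())
    df = (np.count_nonzero(rows) - 1) * (np.count_nonzero(cols) - 1)
    return stat, df


def fisher_exact_rxc(table: np.ndarray) -> float:
    """Freeman-Halton exact test by full enumeration over fixed margins.

    The p value sums the conditional (multivariate hypergeometric)
    probabilities of all tables with the observed margins whose
    probability does not exceed the observed table's (with a small
    relative tolerance against floating-point ties).
    """
    table = np.asarray(table, dtype=int)
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if table.sum() == 0:
        raise ValueError("all-zero contingency table")
    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)
    n = table.sum()

    lf = [math.lgamma(k + 1) for k in range(n + 1)]
    log_const = sum(lf[r] for r in row_sums) + sum(lf[c] for c in col_sums) - lf[n]

    def log_prob(t: np.ndarray) -> float:
        return log_const - sum(lf[v] for v in t.flat)

    p_obs = log_prob(table)
    total = 0.0
    # enumerate the first r-1 rows freely within margins; last row forced
    r, c = table.shape

    def rec(row: int, remaining_cols: np.ndarray, acc: list[np.ndarray]) -> None:
        nonlocal total
        if row == r - 1:
            last = remaining_cols
            if np.any(last < 0):
                return
            t = np.vstack(acc + [last])
            lp = log_prob(t)
            if lp <= p_obs + 1e-9:
                total += math.exp(lp)
            return
        target = row_sums[row]
        ranges = [range(0, min(int(m), int(target)) + 1) for m in remaining_cols[:-1]]
        for combo in itertools.product(*ranges):
            s = sum(combo)
            if s > target:
                continue
            last_cell = target - s
            if last_cell > remaining_cols[-1]:
                continue
            this = np.array(list(combo) + [int(last_cell)])
            rec(row + 1, remaining_cols - this, acc + [this])

    rec(0, col_sums.copy(), [])
    return min(1.0, total)


@dataclass
class BlindingResult:
    table: pd.DataFrame
    correct_proportion: float
    chi2: float
    chi2_df: int
    chi2_p: float
    fisher_p: float

    def to_dict(self) -> dict:
        return {
            "table": self.table.to_dict(),
            "correct_proportion": self.correct_proportion,
            "chi2": self.chi2,
            "chi2_df": self.chi2_df,
            "chi2_p": self.chi2_p,
            "fisher_p": self.fisher_p,
        }


def blinding_table(guesses: pd.DataFrame) -> pd.DataFrame:
    """2x3 counts of true group x guess from a per-participant table."""
    tab = pd.crosstab(guesses["group"], guesses["guess"])
    return tab.reindex(index=["active", "sham"], columns=GUESS_LEVELS, fill_value=0)


def blinding_assessment(table: pd.DataFrame) -> BlindingResult:
    """Correct-guess proportion plus chi-squared and Fisher exact tests.

    A guess is correct when an active participant guesses "Active" or a
    sham participant guesses "Sham"; "I don't know" is never correct.
    """
    arr = table.to_numpy(dtype=int)
    total = arr.sum()
    if total == 0:
        raise ValueError("all-zero blinding table")
    correct = int(
        table.loc["active", "Active"] + table.loc["sham", "Sham"]
    )
    stat, df = chi_squared_statistic(arr)
    return BlindingResult(
        table=table,
        correct_proportion=correct / total,
        chi2=stat,
        chi2_df=df,
        chi2_p=float(sps.chi2.sf(stat, df)) if df > 0 else 1.0,
        fisher_p=fisher_exact_rxc(arr),
    )


@dataclass
class TwoSampleTest:
    variable: str
    mean_active: float
    sd_active: float
    mean_sham: float
    sd_sham: float
    statistic: float
    p: float
    test: str
    note: str = ""


def baseline_comparisons(
    profiles: pd.DataFrame, *, welch: bool = False
) -> list[TwoSampleTest]:
    """Baseline comparability of the two groups.

    Student t-tests (Welch via ``welch=True``) for age, education and
    MoCA; chi-squared for the gender split.  Degenerate (zero-variance)
    variables fall back to an exact equality check.
    """
    a = profiles[profiles["group"] == "active"]
    s = profiles[profiles["group"] == "sham"]
    if len(a) < 2 or len(s) < 2:
        raise ValueError("need at least two participants per group")
    out = []
    for var in ("age", "education", "moca"):
        xa, xs = a[var].to_numpy(float), s[var].to_numpy(float)
        if np.allclose(xa.var(), 0) and np.allclose(xs.var(), 0):
            equal = np.isclose(xa.mean(), xs.mean())
            out.append(
                TwoSampleTest(
                    var, xa.mean(), 0.0, xs.mean(), 0.0,
                    statistic=0.0 if equal else np.inf,
                    p=1.0 if equal else 0.0,
                    test="exact-equality",
                    note="degenerate variance",
                )
            )
            continue
        t, p = sps.ttest_ind(xa, xs, equal_var=not welch)
        out.append(
            TwoSampleTest(
                var,
                float(xa.mean()), float(xa.std(ddof=1)),
                float(xs.mean()), float(xs.std(ddof=1)),
                float(t), float(p),
                test="welch-t" if welch else "student-t",
            )
        )
    tab = pd.crosstab(profiles["group"], profiles["gender"]).to_numpy()
    stat, df = chi_squared_statistic(tab)
    out.append(
        TwoSampleTest(
            "gender",
            float((a["gender"] == "F").sum()), 0.0,
            float((s["gender"] == "F").sum()), 0.0,
            float(stat),
            float(sps.chi2.sf(stat, df)) if df > 0 else 1.0,
            test="chi2",
            note="counts of F per group in mean fields",
        )
    )
    return out


def baseline_table(profiles: pd.DataFrame) -> str:
    """Mean (SD) baseline characteristics table, one row per variable."""
    tests = {t.variable: t for t in baseline_comparisons(profiles)}
    lines = [f"{'':<18}{'Sham tACS':>16}{'Active tACS':>16}{'p value':>10}"]
    label = {"age": "Age, years", "education": "Education, years", "moca": "MoCA"}
    for var in ("age", "education", "moca"):
        t = tests[var]
        lines.append(
            f"{label[var]:<18}"
            f"{f'{t.mean_sham:.1f} ({t.sd_sham:.1f})':>16}"
            f"{f'{t.mean_active:.1f} ({t.sd_active:.1f})':>16}"
            f"{t.p:>10.2f}"
        )
    g = tests["gender"]
    n_a = (profiles["group"] == "active").sum()
    n_s = (profiles["group"] == "sham").sum()
    lines.append(
        f"{'Gender (F/M)':<18}"
        f"{f'{int(g.mean_sham)}/{int(n_s - g.mean_sham)}':>16}"
        f"{f'{int(g.mean_active)}/{int(n_a - g.mean_active)}':>16}"
        f"{g.p:>10.2f}"
    )
    return "\n".join(lines)


def adverse_event_comparison(
    counts: pd.DataFrame, *, categories: list[str] | None = None
) -> list[TwoSampleTest]:
    """Per-category unpaired t-tests on per-session adverse-event counts.

    ``counts`` has one row per group x stimulation session with one
    column per category.  Categories with zero counts in both groups are
    skipped with a note; categories present in only one group are still
    tested but flagged descriptively.
    """
    categories = categories or [c for c in AE_CATEGORIES if c in counts.columns]
    out = []
    for cat in categories:
        xa = counts.loc[counts["group"] == "active", cat].to_numpy(float)
        xs = counts.loc[counts["group"] == "sham", cat].to_numpy(float)
        if len(xa) < 2 or len(xs) < 2:
            raise ValueError("need counts from at least 2 sessions per group")
        if xa.sum() == 0 and xs.sum() == 0:
            out.append(
                TwoSampleTest(
                    cat, 0.0, 0.0, 0.0, 0.0, 0.0, 1.0,
                    test="skipped", note="no events in either group",
                )
            )
            continue
        note = ""
        if xa.sum() == 0 or xs.sum() == 0:
            note = "events in one group only"
        if np.allclose(xa.var(), 0) and np.allclose(xs.var(), 0):
            equal = np.isclose(xa.mean(), xs.mean())
            out.append(
                TwoSampleTest(
                    cat, float(xa.mean()), 0.0, float(xs.mean()), 0.0,
                    0.0 if equal else np.inf, 1.0 if equal else 0.0,
                    test="exact-equality", note="degenerate variance",
                )
            )
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t, p = sps.ttest_ind(xa, xs)
        out.append(
            TwoSampleTest(
                cat,
                float(xa.mean()), float(xa.std(ddof=1)),
                float(xs.mean()), float(xs.std(ddof=1)),
                float(t), float(p), test="student-t", note=note,
            )
        )
    return out
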