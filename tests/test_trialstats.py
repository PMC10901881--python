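"""Blinding, baseline and adverse-event statistics."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from _oracles import chi2_from_scratch, fisher_2x2_enumeration
from tacstrial.trialstats import (
    adverse_event_comparison,
    baseline_comparisons,
    baseline_table,
    blinding_assessment,
    blinding_table,
    chi_squared_statistic,
    fisher_exact_rxc,
)


def _blinding(active_row, sham_row) -> pd.DataFrame:
    return pd.DataFrame(
        [active_row, sham_row],
        index=pd.Index(["active", "sham"], name="group"),
        columns=["Active", "Sham", "I don't know"],
    )


class TestChiSquared:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_from_scratch_and_scipy(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(1, 30, size=(2, 3))
        stat, df = chi_squared_statistic(table)
        assert stat == pytest.approx(chi2_from_scratch(table))
        scipy_stat = sps.chi2_contingency(table, correction=False).statistic
        assert stat == pytest.approx(scipy_stat)
        assert df == 2

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            chi_squared_statistic(np.zeros((2, 2)))


class TestFisherExact:
    @pytest.mark.parametrize("seed", range(8))
    def test_2x2_matches_scipy_and_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(0, 12, size=(2, 2))
        if table.sum() == 0:
            table[0, 0] = 1
        p = fisher_exact_rxc(table)
        assert p == pytest.approx(sps.fisher_exact(table)[1], abs=1e-10)
        assert p == pytest.approx(fisher_2x2_enumeration(table), abs=1e-10)

    def test_independent_margins_give_p_one(self):
        assert fisher_exact_rxc(np.array([[2, 2, 2], [2, 2, 2]])) == pytest.approx(1.0)

    def test_2x3_p_in_unit_interval(self):
        p = fisher_exact_rxc(np.array([[9, 7, 1], [11, 5, 2]]))
        assert 0.0 < p <= 1.0


class TestBlinding:
    def test_study_proportion_18_of_35(self):
        # 18 correct guesses out of 35 completers
        table = _blinding([9, 7, 1], [11, 9, -2])  # placeholder, fixed below
        table = _blinding([10, 6, 1], [8, 8, 2])
        res = blinding_assessment(table)
        assert res.table.to_numpy().sum() == 35
        assert res.correct_proportion == pytest.approx(18 / 35)
        assert round(100 * res.correct_proportion) == 51

    def test_balanced_table_has_zero_chi2(self):
        res = blinding_assessment(_blinding([6, 6, 2], [6, 6, 2]))
        assert res.chi2 == pytest.approx(0.0)
        assert res.chi2_p == pytest.approx(1.0)
        assert res.fisher_p == pytest.approx(1.0)

    def test_crosstab_builder(self):
        guesses = pd.DataFrame(
            {
                "participant_id": ["P1", "P2", "P3"],
                "group": ["active", "active", "sham"],
                "guess": ["Active", "I don't know", "Sham"],
            }
        )
        tab = blinding_table(guesses)
        assert tab.shape == (2, 3)
        assert tab.loc["active", "Active"] == 1
        assert tab.loc["sham", "Sham"] == 1

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            blinding_assessment(_blinding([0, 0, 0], [0, 0, 0]))


def _profiles(n_each=6, identical=True, seed=0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    base = dict(
        age=rng.normal(70, 7, n_each),
        education=rng.normal(13, 3, n_each),
        moca=rng.integers(20, 30, n_each),
    )
    rows = []
    for group in ("active", "sham"):
        vals = base if identical else {
            k: rng.normal(70, 7, n_each) if k == "age" else v
            for k, v in base.items()
        }
        for i in range(n_each):
            rows.append(
                {
                    "participant_id": f"{group}{i}",
                    "group": group,
                    "age": vals["age"][i],
                    "education": vals["education"][i],
                    "moca": vals["moca"][i],
                    "gender": "F" if i % 2 == 0 else "M",
                }
            )
    return pd.DataFrame(rows)


class TestBaseline:
    def test_identical_groups_give_p_one(self):
        results = {t.variable: t for t in baseline_comparisons(_profiles())}
        for var in ("age", "education", "moca"):
            assert results[var].statistic == pytest.approx(0.0, abs=1e-12)
            assert results[var].p == pytest.approx(1.0)
        assert results["gender"].statistic == pytest.approx(0.0)

    def test_null_p_values_are_calibrated(self, default_study):
        _, profiles, _ = default_study
        from tacstrial.cohort import profiles_frame, sample_cohort

        pvals = []
        for seed in range(150):
            df = profiles_frame(sample_cohort(rng_seed=seed))
            pvals.append(
                {t.variable: t.p for t in baseline_comparisons(df)}["age"]
            )
        # groups are drawn from the same distribution: p ~ uniform
        assert sps.kstest(pvals, "uniform").pvalue > 0.01
        assert np.mean(np.array(pvals) < 0.05) < 0.11

    def test_table_formatter_mean_sd_layout(self, default_study):
        _, profiles, _ = default_study
        from tacstrial.cohort import profiles_frame

        text = baseline_table(profiles_frame(profiles))
        assert "Age, years" in text
        assert "Gender (F/M)" in text
        assert "(" in text.splitlines()[1]  # mean (SD) cells

    def test_too_small_groups_rejected(self):
        df = _profiles(n_each=1)
        with pytest.raises(ValueError):
            baseline_comparisons(df)


def _ae_counts(rates_a, rates_s, n_sessions=16, seed=0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    rows = []
    for group, rates in (("active", rates_a), ("sham", rates_s)):
        for s in range(n_sessions):
            row = {"group": group, "stim_session": s + 1}
            row.update({k: rng.poisson(v) for k, v in rates.items()})
            rows.append(row)
    return pd.DataFrame(rows)


class TestAdverseEvents:
    def test_equal_count_vectors_give_p_one(self):
        counts = _ae_counts({"tingling": 10}, {"tingling": 10}, seed=1)
        counts.loc[counts.group == "sham", "tingling"] = counts.loc[
            counts.group == "active", "tingling"
        ].to_numpy()
        res = adverse_event_comparison(counts, categories=["tingling"])[0]
        assert res.p == pytest.approx(1.0)

    def test_zero_in_both_groups_skipped(self):
        counts = _ae_counts({"headache": 0}, {"headache": 0})
        res = adverse_event_comparison(counts, categories=["headache"])[0]
        assert res.test == "skipped"

    def test_one_group_only_flagged(self):
        counts = _ae_counts({"phosphenes": 0}, {"phosphenes": 1.0}, seed=3)
        counts.loc[counts.group == "active", "phosphenes"] = 0
        res = adverse_event_comparison(counts, categories=["phosphenes"])[0]
        assert "one group" in res.note

    def test_type_one_error_rate_under_equal_rates(self):
        n_sig = 0
        for seed in range(300):
            counts = _ae_counts({"tingling": 13}, {"tingling": 13}, seed=seed)
            res = adverse_event_comparison(counts, categories=["tingling"])[0]
            n_sig += res.p < 0.05
        assert n_sig / 300 < 0.10

    def test_too_few_sessions_rejected(self):
        counts = _ae_counts({"tingling": 5}, {"tingling": 5}, n_sessions=1)
        with pytest.raises(ValueError):
            adverse_event_comparison(counts, categories=["tingling"])
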