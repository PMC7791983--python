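"""Improvement reporting, AUC, period sensitivity, report assembly."""

import itertools

import numpy as np
import pandas as pd
import pytest

from promkit import (
    ConfigurationError,
    DegenerateStatisticError,
    InsufficientDataError,
    auc,
    build_report,
    compute_mcid_set,
    observed_improvement,
    period_sensitivity,
    summarize,
)
from promkit.boxcox import fit_boxcox, predict_improvement
from promkit.cohort import TRANSITION_LEVELS, PairedCohort

from conftest import random_cohort


def auc_bruteforce(scores, labels):
    """Exhaustive all-pairs concordance with ties credited 0.5."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p, q in itertools.product(pos, neg):
        total += 1.0 if p > q else 0.5 if p == q else 0.0
    return total / (len(pos) * len(neg))


class TestObservedImprovement:
    def test_all_above_threshold(self, small_cohort):
        assert observed_improvement(small_cohort, 0.0)["total"]["pct"] == 100.0

    def test_threshold_beyond_range(self, small_cohort):
        assert observed_improvement(small_cohort, 99.0)["total"]["pct"] == 0.0

    def test_counting_oracle_per_stratum(self, small_cohort):
        threshold = 12.0
        table = observed_improvement(small_cohort, threshold)
        tr = small_cohort.transition.to_numpy()
        change = small_cohort.change
        for level in TRANSITION_LEVELS:
            cell = table["by_transition"][level]
            mask = tr == level
            assert cell["n"] == mask.sum()
            assert cell["n_improved"] == int((change[mask] >= threshold).sum())

    def test_weighted_stratum_average_equals_total(self, hip_ohs_50k):
        table = observed_improvement(hip_ohs_50k, 22)
        cells = [c for c in table["by_transition"].values() if c is not None]
        weighted = sum(c["pct"] * c["n"] for c in cells) / sum(c["n"] for c in cells)
        assert weighted == pytest.approx(table["total"]["pct"], abs=1e-9)


class TestAuc:
    def test_perfect_separation(self):
        result = auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert result.value == 1.0

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            n = int(rng.integers(8, 50))
            scores = rng.integers(0, 10, n).astype(float)  # ties likely
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            assert auc(scores, labels).value == pytest.approx(
                auc_bruteforce(scores, labels), abs=1e-12
            )

    def test_null_association_near_half(self):
        rng = np.random.default_rng(18)
        scores = rng.normal(size=20_000)
        labels = rng.random(20_000) < 0.4
        assert auc(scores, labels).value == pytest.approx(0.5, abs=0.02)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(19)
        scores = rng.normal(size=500)
        labels = (scores + rng.normal(size=500)) > 0
        a = auc(scores, labels).value
        b = auc(np.exp(3 * scores) + 7, labels).value
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateStatisticError):
            auc([1, 2, 3], [1, 1, 1])

    @pytest.mark.parametrize("method", ["hanley-mcneil", "binomial-exact"])
    def test_ci_brackets_value_within_unit_interval(self, method):
        rng = np.random.default_rng(20)
        scores = rng.normal(size=200)
        labels = (scores + rng.normal(size=200)) > 0
        result = auc(scores, labels, ci_method=method)
        assert 0 <= result.ci_low <= result.value <= result.ci_high <= 1
        assert result.ci_method == method


class TestPeriodSensitivity:
    def test_identical_subsets_give_zero_differences(self):
        cohort = random_cohort(np.random.default_rng(23), n=60)
        df1 = cohort.df.copy()
        df2 = cohort.df.copy()
        df1["period"] = "2009-2011"
        df2["period"] = "2012-2015"
        mirrored = PairedCohort(
            pd.concat([df1, df2], ignore_index=True), cohort.instrument, cohort.joint
        )
        table = period_sensitivity(mirrored, n_boot=0)
        assert (table["difference"].abs() < 1e-12).all()

    def test_planted_shift_detected(self):
        cohort = random_cohort(np.random.default_rng(24), n=400)
        df = cohort.df.copy()
        late = df["period"] == "2012-2015"
        df.loc[late, "post_score"] = np.clip(df.loc[late, "post_score"] + 8, 0, 48)
        shifted = PairedCohort(df, cohort.instrument, cohort.joint)
        table = period_sensitivity(shifted, n_boot=150, seed=6).set_index("statistic")
        row = table.loc["change_mean"]
        assert row["ci_low"] > 0  # CI excludes zero

    def test_null_cohort_differences_cover_zero(self):
        cohort = random_cohort(np.random.default_rng(25), n=600)
        table = period_sensitivity(cohort, n_boot=150, seed=7).set_index("statistic")
        row = table.loc["change_mean"]
        assert row["ci_low"] <= 0 <= row["ci_high"]

    def test_missing_period_is_informative_error(self):
        cohort = random_cohort(np.random.default_rng(26), n=40)
        df = cohort.df.copy()
        df["period"] = "2009-2011"
        single = PairedCohort(df, cohort.instrument, cohort.joint)
        with pytest.raises(InsufficientDataError, match="2012-2015"):
            period_sensitivity(single)


@pytest.fixture(scope="module")
def assembled(hip_ohs_50k):
    summaries = summarize(hip_ohs_50k, by_transition=True, n_boot=0)
    mcids = compute_mcid_set(hip_ohs_50k, summaries[0])
    model = fit_boxcox(hip_ohs_50k)
    predictions = {
        "pre-op": predict_improvement(model, hip_ohs_50k, mcids.paired_mcid_rounded)
    }
    report = build_report(hip_ohs_50k, summaries, mcids, predictions)
    return hip_ohs_50k, summaries, mcids, predictions, report


class TestBuildReport:
    def test_blocks_present_and_percentages_bounded(self, assembled):
        *_, report = assembled
        d = report.to_dict()
        assert {"responsiveness", "thresholds", "improvement", "meta"} <= set(d)
        obs = d["improvement"]["observed"]
        cells = [obs["total"], *obs["by_transition"].values()]
        for cell in cells:
            if cell is not None:
                assert 0 <= cell["pct"] <= 100
                assert cell["n_improved"] <= cell["n"]

    def test_observed_block_matches_observed_improvement(self, assembled):
        cohort, _, mcids, _, report = assembled
        direct = observed_improvement(cohort, mcids.paired_mcid_rounded)
        d = report.to_dict()["improvement"]["observed"]
        assert d["total"]["n_improved"] == direct["total"]["n_improved"]
        for level in TRANSITION_LEVELS:
            assert (
                d["by_transition"][level]["n_improved"]
                == direct["by_transition"][level]["n_improved"]
            )

    def test_observed_percentages_ordered_by_transition(self, assembled):
        """On a calibrated cohort, improvement falls monotonically from
        'much better' to 'much worse'."""
        *_, report = assembled
        obs = report.to_dict()["improvement"]["observed"]["by_transition"]
        pcts = [obs[lv]["pct"] for lv in TRANSITION_LEVELS]
        assert all(a >= b for a, b in zip(pcts, pcts[1:]))

    def test_regeneration_is_byte_identical(self, assembled):
        cohort, summaries, mcids, predictions, report = assembled
        again = build_report(cohort, summaries, mcids, predictions)
        assert again.to_json() == report.to_json()
        assert again.to_markdown() == report.to_markdown()

    def test_auc_present_with_ci(self, assembled):
        *_, report = assembled
        a = report.auc_total
        assert a is not None and 0 <= a.ci_low <= a.value <= a.ci_high <= 1

    def test_provenance_mismatch_refused(self, assembled, hip_eq5d_50k):
        _, summaries, mcids, predictions, _ = assembled
        with pytest.raises(ConfigurationError):
            build_report(hip_eq5d_50k, summaries, mcids, predictions)
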