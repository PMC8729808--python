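import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from methpanel import (
    ValidationError,
    call_cohort,
    default_paper_like_config,
    fisher_exact,
    mann_whitney_u,
    marker_comparison_report,
    mcnemar_test,
    roc,
    sensitivity,
    simulate_ct_cohort,
    specificity,
    wilcoxon_signed_rank,
)
from methpanel.data_model import Group, Location, SampleRecord


def brute_force_auc(cases, controls):
    """Concordant-pair fraction with half credit for ties."""
    wins = ties = 0
    for c in cases:
        for n in controls:
            if c > n:
                wins += 1
            elif c == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(cases) * len(controls))


def brute_force_youden(cases, controls):
    """Best (J, sens, spec) over a grid including ±ε around every score."""
    scores = np.concatenate([cases, controls])
    eps = 1e-9
    grid = np.unique(np.concatenate([scores - eps, scores, scores + eps]))
    best = (-np.inf, None, None)
    for t in grid:
        sens = np.mean(cases >= t)
        spec = np.mean(controls < t)
        j = sens + spec - 1
        if j > best[0] + 1e-12:
            best = (j, sens, spec)
    return best


class TestRates:
    def _records(self, n_case, n_control):
        recs = [SampleRecord(f"C{i}", Group.CRC, Location.rectum, "t")
                for i in range(n_case)]
        recs += [SampleRecord(f"N{i}", Group.normal, Location.unknown, "t")
                 for i in range(n_control)]
        return recs

    @pytest.mark.parametrize(
        "n_pos,n_case,expected",
        [(21, 38, 100 * 21 / 38), (0, 5, 0.0), (17, 17, 100.0)],
    )
    def test_sensitivity_fraction_of_positive_cases(self, n_pos, n_case, expected):
        recs = self._records(n_case, 0)
        calls = pd.Series(
            {f"C{i}": i < n_pos for i in range(n_case)}, dtype="boolean"
        )
        assert sensitivity(calls, recs, "CRC") == pytest.approx(expected)

    def test_specificity_complement_of_control_positivity(self):
        recs = self._records(0, 208)
        calls = pd.Series({f"N{i}": i < 6 for i in range(208)}, dtype="boolean")
        assert specificity(calls, recs, "normal") == pytest.approx(100 * 202 / 208)

    def test_no_valid_samples_is_error(self):
        recs = self._records(1, 0)
        with pytest.raises(ValidationError):
            sensitivity(pd.Series(dtype="boolean"), recs, "CRC")


class TestRoc:
    def test_perfect_separation(self):
        scores = [1, 2, 3, 10, 11, 12]
        labels = [False] * 3 + [True] * 3
        r = roc(scores, labels, "higher_score_is_positive")
        assert r.auc == 1.0
        assert r.sensitivity_at_cutoff == 100.0
        assert r.specificity_at_cutoff == 100.0

    def test_all_ties_gives_half(self):
        r = roc([5.0] * 8, [True] * 4 + [False] * 4, "higher_score_is_positive")
        assert r.auc == pytest.approx(0.5)

    def test_auc_equals_exhaustive_pair_count_on_random_instances(self, rng):
        for _ in range(200):
            n1, n0 = rng.integers(2, 15, size=2)
            # integer scores force plenty of ties
            cases = rng.integers(0, 8, size=n1).astype(float)
            controls = rng.integers(0, 8, size=n0).astype(float)
            scores = np.concatenate([cases, controls])
            labels = np.array([True] * n1 + [False] * n0)
            r = roc(scores, labels, "higher_score_is_positive")
            assert r.auc == pytest.approx(brute_force_auc(cases, controls))

    def test_youden_cutoff_matches_exhaustive_grid(self, rng):
        for _ in range(50):
            cases = rng.normal(1, 1, size=12)
            controls = rng.normal(0, 1, size=15)
            r = roc(np.concatenate([cases, controls]),
                    [True] * 12 + [False] * 15, "higher_score_is_positive")
            j_ref, _, _ = brute_force_youden(cases, controls)
            j_got = (r.sensitivity_at_cutoff + r.specificity_at_cutoff) / 100 - 1
            assert j_got == pytest.approx(j_ref, abs=1e-9)

    def test_orientation_flip_with_negated_scores_is_invariant(self, rng):
        scores = rng.normal(size=30)
        labels = rng.random(30) < 0.5
        labels[0], labels[1] = True, False
        a = roc(scores, labels, "higher_score_is_positive")
        b = roc(-scores, labels, "lower_score_is_positive")
        assert a.auc == pytest.approx(b.auc)
        assert a.ci_low == pytest.approx(b.ci_low)
        assert a.sensitivity_at_cutoff == pytest.approx(b.sensitivity_at_cutoff)
        assert a.specificity_at_cutoff == pytest.approx(b.specificity_at_cutoff)
        assert a.optimal_cutoff == pytest.approx(-b.optimal_cutoff)

    def test_delong_ci_matches_independent_reference(self):
        # expected values frozen from R pROC ci.auc(..., method="delong")
        cases = [3.1, 2.7, 3.9, 2.2, 4.5, 3.3, 2.9, 3.8, 1.9, 4.1, 3.0, 2.5]
        controls = [1.2, 2.1, 0.8, 1.9, 2.6, 1.1, 0.5, 2.3, 1.7, 0.9, 1.4, 2.0,
                    1.6, 0.7]
        r = roc(cases + controls, [True] * 12 + [False] * 14,
                "higher_score_is_positive")
        assert r.auc == pytest.approx(0.9553571429, abs=1e-9)
        assert r.ci_low == pytest.approx(0.8868044775, abs=1e-9)
        assert r.ci_high == pytest.approx(1.0, abs=1e-9)

    def test_bootstrap_ci_brackets_auc_and_is_seeded(self, rng):
        scores = rng.normal(size=40) + np.r_[np.ones(20), np.zeros(20)]
        labels = [True] * 20 + [False] * 20
        a = roc(scores, labels, "higher_score_is_positive",
                ci_method="bootstrap", n_boot=200, seed=5)
        b = roc(scores, labels, "higher_score_is_positive",
                ci_method="bootstrap", n_boot=200, seed=5)
        assert a.ci_low <= a.auc <= a.ci_high
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc([1, 2, 3], [True, True, True], "higher_score_is_positive")


def fisher_oracle(a, b, c, d):
    """Two-sided p by full hypergeometric enumeration with fixed margins."""
    r1, c1, N = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - N), min(r1, c1)
    pmf = {k: scipy.stats.hypergeom.pmf(k, N, c1, r1) for k in range(lo, hi + 1)}
    p_obs = pmf[a]
    return sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-7))


class TestFisherExact:
    def test_symmetric_table_is_one(self):
        assert fisher_exact([[1, 1], [1, 1]]) == pytest.approx(1.0)

    def test_subsite_contrast_matches_enumeration(self):
        # left-colon vs right-colon carcinoma counts
        assert fisher_exact([[5, 3], [1, 3]]) == pytest.approx(
            fisher_oracle(5, 3, 1, 3), rel=1e-9
        )

    def test_extreme_table_closed_form(self):
        assert fisher_exact([[0, 10], [10, 0]]) == pytest.approx(
            2 / math.comb(20, 10), rel=1e-9
        )

    def test_zero_margin_is_one_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="methpanel"):
            assert fisher_exact([[0, 0], [3, 4]]) == 1.0
        assert "zero margin" in caplog.text

    def test_matches_enumeration_on_random_tables(self, rng):
        for _ in range(300):
            a, b, c, d = rng.integers(0, 11, size=4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            assert fisher_exact([[a, b], [c, d]]) == pytest.approx(
                fisher_oracle(a, b, c, d), rel=1e-7
            )


class TestRankTests:
    def test_identical_groups_u_is_half_of_products(self):
        x = [1.0, 2.0, 3.0, 4.0]
        u, p = mann_whitney_u(x, list(x))
        assert u == pytest.approx(len(x) ** 2 / 2)
        assert p > 0.9

    def test_separated_groups_exact_enumeration(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(2 / math.comb(6, 3), rel=1e-9)

    def test_wilcoxon_all_positive_unit_differences(self):
        n = 8
        x = np.arange(n, dtype=float)
        w, p = wilcoxon_signed_rank(x + 1.0, x)
        assert p == pytest.approx(2 * (1 / 2**n), rel=1e-9)

    def test_wilcoxon_all_zero_differences_is_error(self):
        with pytest.raises(ValidationError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    def test_mcnemar_is_symmetric_binomial(self):
        # discordant pairs 6 vs 6 -> p = 1
        assert mcnemar_test([[10, 6], [6, 10]]) == pytest.approx(1.0)


@pytest.fixture(scope="module")
def cohort_report():
    _, cfg = default_paper_like_config()
    table, records, _ = simulate_ct_cohort(cfg, seed=11)
    calls = call_cohort(table)
    return marker_comparison_report(calls, records), records


class TestMarkerComparisonReport:

    def test_dual_sensitivity_at_least_each_single(self, cohort_report):
        report, _ = cohort_report
        s = report.summary
        for grp in s["group"].unique():
            sub = s[(s["group"] == grp) & (s["indicator"] == "Ct")]
            dual = float(sub.loc[sub["markers"] == "SDC2/TFPI2", "sens_fixed"].iloc[0])
            for g in ("SDC2", "TFPI2"):
                single = float(sub.loc[sub["markers"] == g, "sens_fixed"].iloc[0])
                assert dual >= single

    def test_dual_specificity_at_most_each_single(self, cohort_report):
        report, _ = cohort_report
        s = report.summary
        for grp in s["group"].unique():
            sub = s[(s["group"] == grp) & (s["indicator"] == "Ct")]
            dual = float(sub.loc[sub["markers"] == "SDC2/TFPI2", "spec_fixed"].iloc[0])
            for g in ("SDC2", "TFPI2"):
                single = float(sub.loc[sub["markers"] == g, "spec_fixed"].iloc[0])
                assert dual <= single

    def test_summary_covers_all_cells(self, cohort_report):
        report, _ = cohort_report
        s = report.summary
        assert len(s) == 3 * 2 * 3  # comparisons x indicators x marker sets
        assert ((s["ci_low"] <= s["auc"]) & (s["auc"] <= s["ci_high"])).all()

    def test_by_location_counts_sum_to_total(self, cohort_report):
        report, _ = cohort_report
        bl = report.by_location
        for grp in bl["group"].unique():
            sub = bl[bl["group"] == grp]
            total = int(sub.loc[sub["location"] == "Total", "n"].iloc[0])
            assert sub.loc[sub["location"] != "Total", "n"].sum() == total

    def test_identical_single_and_dual_calls_give_identical_rows(self):
        # cohort where TFPI2 never fires: dual == SDC2 alone
        _, cfg = default_paper_like_config()
        cfg.complement_meth_prob = 0.0
        cfg.complement_given_anchor_neg = 0.0
        cfg.no_amp_prob = 1.0
        table, records, _ = simulate_ct_cohort(cfg, seed=2)
        calls = call_cohort(table)
        rep = marker_comparison_report(calls, records)
        s = rep.summary
        sub = s[s["indicator"] == "Ct"]
        for grp in sub["group"].unique():
            g = sub[sub["group"] == grp]
            dual = g.loc[g["markers"] == "SDC2/TFPI2"].iloc[0]
            single = g.loc[g["markers"] == "SDC2"].iloc[0]
            assert dual["sens_fixed"] == single["sens_fixed"]
            assert dual["spec_fixed"] == single["spec_fixed"]
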