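import math

import numpy as np
import pandas as pd
import pytest

from organoidscreen import (
    abundance_filter,
    cohens_d,
    enrichment_timecourse,
    exceedance_fraction,
    fdr_adjust,
    fisher_enrichment,
    generate_composition_counts,
    minmax_scale,
)


def fisher_p_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration:
    sum of the probabilities of all tables (with the same margins) no
    more probable than the observed one."""
    m1, m2, k = a + b, c + d, a + c

    def log_prob(x):
        return (
            math.lgamma(m1 + 1) - math.lgamma(x + 1) - math.lgamma(m1 - x + 1)
            + math.lgamma(m2 + 1) - math.lgamma(k - x + 1) - math.lgamma(m2 - k + x + 1)
            - (math.lgamma(m1 + m2 + 1) - math.lgamma(k + 1) - math.lgamma(m1 + m2 - k + 1))
        )

    lo, hi = max(0, k - m2), min(k, m1)
    probs = {x: math.exp(log_prob(x)) for x in range(lo, hi + 1)}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))


def _table(rows):
    return pd.DataFrame(rows, columns=["condition", "stratum", "cell_type", "n_cells"])


class TestAbundanceFilter:
    def test_fraction_mode_requires_both_conditions(self):
        table = _table(
            [
                ("control", 0, "paneth", 10),
                ("control", 0, "rest", 990),
                ("treated", 0, "paneth", 4),
                ("treated", 0, "rest", 996),
            ]
        )
        out = abundance_filter(table).set_index("cell_type")
        assert not out.loc["paneth", "eligible"]  # 0.4% in treated
        assert "treated" in out.loc["paneth", "filter_reason"]

    def test_exactly_at_threshold_is_eligible(self):
        table = _table(
            [
                ("control", 0, "paneth", 5),
                ("control", 0, "rest", 995),
                ("treated", 0, "paneth", 5),
                ("treated", 0, "rest", 995),
            ]
        )
        out = abundance_filter(table).set_index("cell_type")
        assert out.loc["paneth", "eligible"]

    def test_count_mode(self):
        table = _table(
            [
                ("control", 0, "paneth", 9),
                ("control", 0, "rest", 991),
                ("treated", 0, "paneth", 50),
                ("treated", 0, "rest", 950),
            ]
        )
        out = abundance_filter(table, mode="count").set_index("cell_type")
        assert not out.loc["paneth", "eligible"]
        assert abundance_filter(table, mode="count", min_cells=9).set_index(
            "cell_type"
        ).loc["paneth", "eligible"]


class TestFisherEnrichment:
    def test_cross_product_example(self):
        res = fisher_enrichment(30, 70, 15, 85)
        assert res.odds_ratio == pytest.approx((30 * 85) / (70 * 15), rel=1e-12)
        assert res.odds_ratio == pytest.approx(2.4286, abs=1e-4)
        assert res.p == pytest.approx(fisher_p_oracle(30, 70, 15, 85), rel=1e-9)
        assert res.ci_low < res.odds_ratio < res.ci_high

    def test_proportional_table_is_null(self):
        res = fisher_enrichment(20, 80, 10, 40)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_condition_transpose_inverts_or(self):
        fwd = fisher_enrichment(30, 70, 15, 85)
        rev = fisher_enrichment(15, 85, 30, 70)
        assert rev.odds_ratio == pytest.approx(1 / fwd.odds_ratio, rel=1e-12)
        assert rev.p == pytest.approx(fwd.p, rel=1e-12)

    def test_zero_cell_gets_haldane_correction(self):
        res = fisher_enrichment(0, 100, 10, 90)
        expected = (0.5 * 90.5) / (100.5 * 10.5)
        assert res.odds_ratio == pytest.approx(expected, rel=1e-12)
        assert np.isfinite(res.ci_low) and res.ci_low > 0

    def test_empty_margin_untested(self):
        res = fisher_enrichment(0, 0, 10, 90)
        assert not res.tested and "margin" in res.filter_reason

    def test_matches_enumeration_on_small_margins(self):
        """Implementation p equals exhaustive enumeration for a sweep of
        small tables (full margins <= 30 sweep in the acceptance suite)."""
        for a in range(0, 13, 3):
            for b in range(1, 13, 4):
                for c in range(1, 13, 4):
                    for d in range(0, 13, 3):
                        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                            continue
                        res = fisher_enrichment(a, b, c, d)
                        assert res.p == pytest.approx(
                            fisher_p_oracle(a, b, c, d), rel=1e-9
                        ), (a, b, c, d)


class TestTimecourse:
    def test_ineligible_strata_reported_untested(self):
        table = _table(
            [
                ("control", 0, "paneth", 2),
                ("control", 0, "rest", 998),
                ("treated", 0, "paneth", 30),
                ("treated", 0, "rest", 970),
                ("control", 1, "paneth", 30),
                ("control", 1, "rest", 970),
                ("treated", 1, "paneth", 60),
                ("treated", 1, "rest", 940),
            ]
        )
        out = enrichment_timecourse(table)
        by = out.set_index(["cell_type", "stratum"])
        assert not by.loc[("paneth", 0), "tested"]
        assert by.loc[("paneth", 0), "filter_reason"]
        assert by.loc[("paneth", 1), "tested"]
        assert by.loc[("paneth", 1), "q"] <= 1.0

    def test_ci_coverage_of_designed_or(self):
        """95% Woolf CIs cover the designed odds ratio at close to the
        nominal rate over seeded simulated tables."""
        base = {"paneth": 0.2, "stem": 0.5, "goblet": 0.3}
        covered = 0
        n_rep = 150
        for seed in range(n_rep):
            table, _ = generate_composition_counts(
                seed, 1, base, {("paneth", 0): 2.0}, 10_000
            )
            out = enrichment_timecourse(table.rename(columns={"timepoint": "stratum"}))
            row = out.set_index("cell_type").loc["paneth"]
            if row["ci_low"] <= 2.0 <= row["ci_high"]:
                covered += 1
        assert covered / n_rep >= 0.93

    def test_null_design_q_calibration(self):
        """With no designed enrichment anywhere, the fraction of
        q < 0.05 calls stays at or below 0.05 across seeds."""
        base = {"a": 0.25, "b": 0.25, "c": 0.25, "d": 0.25}
        calls, total = 0, 0
        for seed in range(40):
            table, _ = generate_composition_counts(seed + 1000, 2, base, None, 2000)
            out = enrichment_timecourse(table.rename(columns={"timepoint": "stratum"}))
            calls += int((out.loc[out["tested"], "q"] < 0.05).sum())
            total += int(out["tested"].sum())
        assert calls / total <= 0.05


class TestFdrAdjust:
    def test_bh_step_up_by_hand(self):
        q = fdr_adjust(np.array([0.01, 0.02, 0.03]), "bh")
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert fdr_adjust(np.array([0.04]), "bh")[0] == pytest.approx(0.04)

    def test_bonferroni_capped(self):
        q = fdr_adjust(np.array([0.01, 0.5, 1.0]), "bonferroni")
        assert np.allclose(q, [0.03, 1.0, 1.0])

    def test_bh_never_below_raw_and_monotone(self, rng):
        p = rng.uniform(size=30)
        q = fdr_adjust(p, "bh")
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust(np.array([0.5, 1.2]), "bh")


class TestCohensD:
    def test_identical_groups_negligible(self):
        res = cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.cohens_d == 0.0 and res.magnitude_bin == "negligible"

    def test_zero_pooled_sd_undefined(self):
        with pytest.raises(ValueError, match="pooled SD"):
            cohens_d([0.0, 0.0], [1.0, 1.0])

    def test_one_pooled_sd_shift_is_medium(self, rng):
        y = rng.normal(0, 1, 500)
        x = y + 1.0  # identical spread, shift exactly one pooled SD? no -
        # construct exactly: pooled SD of (y, y+s) equals SD of y
        s = float(np.std(y, ddof=1))
        x = y + s
        res = cohens_d(x, y)
        assert res.cohens_d == pytest.approx(1.0, rel=1e-12)
        assert res.magnitude_bin == "medium" and res.magnitude_symbol == "$$"

    @pytest.mark.parametrize(
        "d,bin_name",
        [(0.3, "negligible"), (0.6, "small"), (1.0, "medium"),
         (1.5, "large"), (2.5, "very large"), (-2.5, "very large")],
    )
    def test_magnitude_bins(self, rng, d, bin_name):
        y = rng.normal(0, 1, 2000)
        s = float(np.std(y, ddof=1))
        res = cohens_d(y + d * s, y)
        assert res.magnitude_bin == bin_name


class TestScalingAndExceedance:
    def test_minmax_examples(self):
        assert np.allclose(minmax_scale([2.0, 4.0, 6.0]), [0.0, 0.5, 1.0])
        out = minmax_scale(np.random.default_rng(1).normal(size=50))
        assert out.min() == 0.0 and out.max() == 1.0

    def test_minmax_affine_invariance(self, rng):
        x = rng.normal(size=20)
        assert np.allclose(minmax_scale(x), minmax_scale(3.5 * x - 2.0))

    def test_minmax_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            minmax_scale([1.0, 1.0])

    def test_exceedance_hand_count(self):
        ref = [2, 3, 3, 3, 4, 4, 4, 4, 4, 5]
        cutoff, frac = exceedance_fraction(ref, [5, 6, 4, 3, 5])
        assert cutoff == 4
        assert frac == pytest.approx(3 / 5)

    def test_exceedance_none_above(self):
        cutoff, frac = exceedance_fraction([2, 3, 4], [1, 2, 3, 4])
        assert frac == 0.0

    def test_percentile_zero_gives_min(self):
        cutoff, _ = exceedance_fraction([7, 2, 5], [0], percentile=0)
        assert cutoff == 2

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            exceedance_fraction([], [1])
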