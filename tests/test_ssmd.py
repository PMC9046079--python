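import math

import numpy as np
import pandas as pd
import pytest

from organoidscreen import (
    DecisionParams,
    WeightSpec,
    fnl_curve,
    fpl_curve,
    fold_change_zscores,
    noncentral_t_cdf,
    optimal_critical_value,
    pool_variance,
    replicate_ssmd,
    score_groups,
    simulate_ssmd_groups,
    summarize_groups,
    umvue_factor,
)


def _normalized_frame(fcs_by_donor, treatment="C1", dose=1.0, assay="LYZ.NS"):
    rows = []
    for i, (donor, fc) in enumerate(fcs_by_donor):
        rows.append(
            {
                "role": "COMPOUND",
                "treatment_id": treatment,
                "dose_uM": dose,
                "assay": assay,
                "donor": donor,
                "fold_change": fc,
            }
        )
    return pd.DataFrame(rows)


class TestSummaries:
    def test_mean_and_variance(self):
        frame = _normalized_frame([("m1", 0.2), ("m2", 0.4), ("m3", 0.6)])
        out = summarize_groups(frame)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["n"] == 3
        assert row["d_bar"] == pytest.approx(0.4)
        assert row["s2"] == pytest.approx(0.04)
        assert bool(row["scored"])

    def test_single_replicate_flagged_not_dropped(self):
        frame = _normalized_frame([("m1", 0.2)])
        out = summarize_groups(frame)
        assert len(out) == 1 and not bool(out.iloc[0]["scored"])

    def test_replicate_order_irrelevant(self):
        a = summarize_groups(_normalized_frame([("m1", 0.1), ("m2", 0.5), ("m3", 0.3)]))
        b = summarize_groups(_normalized_frame([("m3", 0.3), ("m1", 0.1), ("m2", 0.5)]))
        pd.testing.assert_frame_equal(a, b)

    def test_donor_with_multiple_wells_averaged(self):
        frame = _normalized_frame(
            [("m1", 0.0), ("m1", 0.4), ("m2", 0.2), ("m3", 0.2)]
        )
        out = summarize_groups(frame)
        assert out.iloc[0]["n"] == 3
        assert out.iloc[0]["d_bar"] == pytest.approx(0.2)

    def test_well_replicate_unit(self):
        frame = _normalized_frame([("m1", 0.1), ("m1", 0.2), ("m1", 0.3)])
        out = summarize_groups(frame, replicate="well")
        assert out.iloc[0]["n"] == 3


class TestVariancePool:
    def test_median_examples(self):
        groups = pd.DataFrame(
            {"assay": "A", "s2": [0.01, 0.04, 0.09], "scored": True}
        )
        assert pool_variance(groups, "A").s0_sq == pytest.approx(0.04)
        even = pd.DataFrame({"assay": "A", "s2": [0.01, 0.04], "scored": True})
        assert pool_variance(even, "A").s0_sq == pytest.approx(0.025)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            pool_variance(pd.DataFrame({"assay": [], "s2": [], "scored": []}), "A")


class TestReplicateSSMD:
    def test_hand_computed_value(self):
        """n=3, d_bar=0.4, s2=s0^2=0.04, w=0.5/0.5 -> c_3 * 0.4 / 0.2
        with c_3 = Gamma(1)/Gamma(1/2) * sqrt(2/2) = 1/sqrt(pi)."""
        c3 = math.gamma(1.0) / math.gamma(0.5) * math.sqrt(1.0)
        assert umvue_factor(3) == pytest.approx(c3, rel=1e-12)
        got = replicate_ssmd(0.4, 0.04, 3, 0.04)
        assert got == pytest.approx(2 / math.sqrt(math.pi), rel=1e-12)
        assert got == pytest.approx(1.1284, abs=1e-4)

    def test_zero_mean_gives_zero(self):
        assert replicate_ssmd(0.0, 0.3, 3, 0.1) == 0.0

    def test_antisymmetry_and_scale_invariance(self):
        base = replicate_ssmd(0.4, 0.04, 3, 0.09)
        assert replicate_ssmd(-0.4, 0.04, 3, 0.09) == pytest.approx(-base)
        lam = 7.3
        scaled = replicate_ssmd(0.4 * lam, 0.04 * lam**2, 3, 0.09 * lam**2)
        assert scaled == pytest.approx(base, rel=1e-12)

    def test_zero_denominator_flagged_nan(self):
        assert np.isnan(replicate_ssmd(0.4, 0.0, 3, 0.0))

    def test_umvue_factor_requires_n3(self):
        with pytest.raises(ValueError):
            umvue_factor(2)


class TestZScores:
    def test_examples(self):
        z = fold_change_zscores(np.array([-1.0, 0.0, 1.0]))
        assert z[-1] == pytest.approx(1.0)  # sample SD of {-1,0,1} is 1
        assert z[1] == 0.0
        z2 = fold_change_zscores(np.array([0.3, 0.0, 0.15, -0.15, -0.3]))
        sd = np.std([0.3, 0.0, 0.15, -0.15, -0.3], ddof=1)
        assert z2[0] == pytest.approx(0.3 / sd)

    def test_degenerate_populations_flagged(self):
        assert np.isnan(fold_change_zscores(np.array([0.5]))).all()
        assert np.isnan(fold_change_zscores(np.array([0.5, 0.5]))).all()


class TestScoreGroups:
    def test_pooling_scope_is_per_assay(self):
        rows = []
        for assay, s2 in [("LYZ.NS", 0.01), ("LYZ.NS", 0.09), ("LYZ.S", 1.0)]:
            rows.append(
                {
                    "treatment_id": f"C{len(rows)}",
                    "dose_uM": 1.0,
                    "assay": assay,
                    "n": 3,
                    "d_bar": 0.1 * (len(rows) + 1),
                    "s2": s2,
                    "scored": True,
                }
            )
        out = score_groups(pd.DataFrame(rows))
        assert np.allclose(out.loc[out["assay"] == "LYZ.NS", "s0_sq"], 0.05)
        assert np.allclose(out.loc[out["assay"] == "LYZ.S", "s0_sq"], 1.0)

    def test_unscored_groups_keep_nan(self):
        frame = pd.DataFrame(
            [
                {"treatment_id": "C1", "dose_uM": 1.0, "assay": "A", "n": 1,
                 "d_bar": 0.5, "s2": 0.0, "scored": False},
                {"treatment_id": "C2", "dose_uM": 1.0, "assay": "A", "n": 3,
                 "d_bar": 0.5, "s2": 0.1, "scored": True},
                {"treatment_id": "C3", "dose_uM": 1.0, "assay": "A", "n": 3,
                 "d_bar": 0.2, "s2": 0.2, "scored": True},
            ]
        )
        out = score_groups(frame)
        assert np.isnan(out.loc[out["treatment_id"] == "C1", "ssmd"]).all()
        assert out.loc[out["treatment_id"] != "C1", "ssmd"].notna().all()


class TestNoncentralT:
    def test_central_symmetry_and_limits(self):
        assert noncentral_t_cdf(0.0, 5, 0.0) == pytest.approx(0.5)
        assert noncentral_t_cdf(1e9, 5, 2.0) == pytest.approx(1.0)
        assert noncentral_t_cdf(-1e9, 5, 2.0) == pytest.approx(0.0)

    def test_matches_monte_carlo_oracle(self, rng):
        """T = (Z + ncp)/sqrt(V/df): the CDF matches simulation within
        3 SE on a grid of (x, df, ncp)."""
        n = 200_000
        for df in (2, 7):
            for ncp in (0.43, 3.0 * math.sqrt(3)):
                z = rng.standard_normal(n)
                v = rng.chisquare(df, n)
                t = (z + ncp) / np.sqrt(v / df)
                for x in (0.5, 2.0, 3.5):
                    emp = float(np.mean(t <= x))
                    # guard absorbs Poisson error in near-degenerate tails
                    se = math.sqrt(max(emp * (1 - emp), 1e-12) / n)
                    got = noncentral_t_cdf(x, df, ncp)
                    assert abs(got - emp) < 3 * se + 1e-5


class TestDecisionCurves:
    def test_fpl_central_at_zero(self):
        params = DecisionParams(n=3, beta2=0.0)
        assert fpl_curve(0.0, params) == pytest.approx(0.5)

    def test_monotonicity(self):
        params = DecisionParams(n=3)
        assert fpl_curve(0.5, params) > fpl_curve(1.5, params)
        assert fnl_curve(0.5, params) < fnl_curve(1.5, params)

    def test_error_levels_at_printed_threshold(self):
        """Both error curves evaluate to ~0.084 at the primary-design
        critical value 0.997."""
        params = DecisionParams(n=3)
        assert fpl_curve(0.997, params) == pytest.approx(0.084, abs=1e-3)
        assert fnl_curve(0.997, params) == pytest.approx(0.084, abs=1e-3)


class TestOptimalCriticalValue:
    def test_primary_intersection(self):
        solved = optimal_critical_value(DecisionParams(n=3))
        assert solved.beta_alpha1 == pytest.approx(0.997, abs=5e-4)
        assert solved.achieved_fpl == pytest.approx(solved.achieved_fnl, abs=1e-5)
        assert solved.achieved_fpl == pytest.approx(0.084, abs=1e-3)

    def test_validation_fpl_only(self):
        solved = optimal_critical_value(
            DecisionParams(n=8, fpl=0.05), mode="fpl_only"
        )
        assert solved.beta_alpha1 == pytest.approx(0.889, abs=1e-3)
        assert solved.achieved_fpl == pytest.approx(0.05, abs=1e-6)

    def test_raw_scale_variant_differs(self):
        umvue = optimal_critical_value(DecisionParams(n=3))
        raw = optimal_critical_value(DecisionParams(n=3, scale="raw"))
        assert raw.beta_alpha1 == pytest.approx(
            umvue.beta_alpha1 / umvue.c_n, rel=1e-4
        )

    def test_threshold_monotone_in_target_fpl(self):
        """Brute-force grid check: stricter FPL targets push the
        critical value up."""
        grid = np.linspace(0.01, 3.0, 400)
        params = DecisionParams(n=8, fpl=0.01)
        fpls = np.array([fpl_curve(b, params) for b in grid])
        assert (np.diff(fpls) < 0).all()
        b_strict = optimal_critical_value(params, mode="fpl_only").beta_alpha1
        b_loose = optimal_critical_value(
            DecisionParams(n=8, fpl=0.10), mode="fpl_only"
        ).beta_alpha1
        assert b_strict > b_loose
        # solver agrees with the grid inversion to grid resolution
        assert abs(grid[np.argmin(np.abs(fpls - 0.01))] - b_strict) < 0.01

    def test_bracket_without_sign_change_errors(self):
        with pytest.raises(ValueError, match="sign change"):
            optimal_critical_value(
                DecisionParams(n=3, fpl=0.05), mode="fpl_only", bracket=(5.0, 20.0)
            )

    def test_intersect_requires_ordered_bounds(self):
        with pytest.raises(ValueError, match="beta1 > beta2"):
            optimal_critical_value(DecisionParams(n=3, beta1=0.1, beta2=0.25))

    def test_solver_stable_to_bracket(self):
        a = optimal_critical_value(DecisionParams(n=3), bracket=(1e-9, 20.0))
        b = optimal_critical_value(DecisionParams(n=3), bracket=(0.1, 5.0))
        assert a.beta_alpha1 == pytest.approx(b.beta_alpha1, abs=2e-6)


def test_umvue_unbiasedness_quick(rng):
    """Mean estimated SSMD tracks the true effect (larger-n version in
    the acceptance suite)."""
    for beta in (0.0, 1.0):
        ssmds = simulate_ssmd_groups(rng, 20_000, n=3, beta=beta)
        assert abs(float(np.mean(ssmds)) - beta) < 0.05


def test_weightspec_constraint():
    with pytest.raises(ValueError):
        WeightSpec(w_i=0.7, w_0=0.5)
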