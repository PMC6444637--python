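"""Agreement statistics: CCC, Bland-Altman, kappas, chi-square, report builder."""

import numpy as np
import pandas as pd
import pytest

from actiwear import (
    InsufficientDataError,
    PairedPanel,
    UndefinedStatisticError,
    bland_altman,
    build_comparison_tables,
    ccc_repeated,
    cohen_kappa,
    interpret_ccc,
    lin_ccc,
    mean_difference_ci,
    two_proportion_test,
    weighted_kappa,
)

from oracles import (
    kappa_oracle,
    lin_ccc_oracle,
    linear_weights,
    pearson_chi2_oracle,
)


def panel_from_matrix(ref: np.ndarray, comp: np.ndarray) -> PairedPanel:
    """Build a panel from (n_subjects, n_days) matrices."""
    n, k = ref.shape
    subjects = np.repeat([f"S{i:03d}" for i in range(n)], k)
    days = np.tile(np.arange(1, k + 1), n)
    return PairedPanel(subjects, days, ref.ravel(), comp.ravel())


def simulate_panel(rng, n=30, k=4, s2_s=100.0, s2_sd=25.0, s2_sm=4.0, s2_e=9.0, delta=0.0):
    """Draw from the two-method repeated-measures model; the true CCC is
    (s2_s + s2_sd) / (s2_s + s2_sd + s2_sm + s2_e + delta^2/2)."""
    subj = rng.normal(0, np.sqrt(s2_s), size=(n, 1, 1))
    sd = rng.normal(0, np.sqrt(s2_sd), size=(n, k, 1))
    sm = rng.normal(0, np.sqrt(s2_sm), size=(n, 1, 2))
    e = rng.normal(0, np.sqrt(s2_e), size=(n, k, 2))
    y = 500.0 + subj + sd + sm + e
    y[..., 1] += delta
    return y[..., 0], y[..., 1]


def true_ccc(s2_s=100.0, s2_sd=25.0, s2_sm=4.0, s2_e=9.0, delta=0.0):
    num = s2_s + s2_sd
    return num / (num + s2_sm + s2_e + 0.5 * delta**2)


class TestCCC:
    def test_identical_methods_give_perfect_concordance(self, rng):
        ref = rng.normal(600, 100, size=(20, 4))
        res = ccc_repeated(panel_from_matrix(ref, ref.copy()), n_boot=50, seed=1)
        assert res.estimate == pytest.approx(1.0, abs=1e-12)
        assert res.interpretation == "excellent"

    def test_single_day_panel_equals_lin_closed_form(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 40))
            x = rng.normal(500, 80, size=(n, 1))
            y = 0.8 * x + rng.normal(20, 30, size=(n, 1))
            res = ccc_repeated(panel_from_matrix(x, y), n_boot=0)
            assert res.estimate == pytest.approx(lin_ccc_oracle(x.ravel(), y.ravel()), abs=1e-6)
            assert lin_ccc(x.ravel(), y.ravel()) == pytest.approx(res.estimate, abs=1e-6)

    def test_constant_shift_lowers_concordance_toward_closed_form(self, rng):
        estimates = []
        for delta in (0.0, 10.0, 20.0):
            ref, comp = simulate_panel(rng, n=400, k=4, delta=delta)
            res = ccc_repeated(panel_from_matrix(ref, comp), n_boot=0)
            estimates.append(res.estimate)
            assert res.estimate == pytest.approx(true_ccc(delta=delta), abs=0.06)
        assert estimates[0] > estimates[1] > estimates[2]

    def test_recovers_generating_model_ccc(self, rng):
        ref, comp = simulate_panel(rng, n=500, k=4, s2_sm=16.0, s2_e=25.0)
        res = ccc_repeated(panel_from_matrix(ref, comp), n_boot=0)
        assert res.estimate == pytest.approx(true_ccc(s2_sm=16.0, s2_e=25.0), abs=0.05)

    def test_bootstrap_is_reproducible_and_brackets_estimate(self, rng):
        ref, comp = simulate_panel(rng, n=25, k=4)
        panel = panel_from_matrix(ref, comp)
        a = ccc_repeated(panel, n_boot=200, seed=42)
        b = ccc_repeated(panel, n_boot=200, seed=42)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        assert a.ci_low <= a.estimate <= a.ci_high

    def test_unbalanced_panel_uses_complete_pairs(self, rng):
        ref, comp = simulate_panel(rng, n=20, k=4)
        comp[3, 2] = np.nan  # lost day
        res = ccc_repeated(panel_from_matrix(ref, comp), n_boot=0)
        assert 0 < res.estimate <= 1
        assert res.n_pairs == 79

    def test_too_few_subjects_rejected(self):
        panel = PairedPanel(["A"] * 3, [1, 2, 3], [1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        with pytest.raises(InsufficientDataError):
            ccc_repeated(panel)

    def test_zero_variance_is_undefined(self):
        panel = panel_from_matrix(np.full((5, 2), 7.0), np.full((5, 2), 7.0))
        with pytest.raises(UndefinedStatisticError):
            ccc_repeated(panel)

    @pytest.mark.parametrize(
        "value, band",
        [(0.2, "low"), (0.449, "low"), (0.45, "reasonably_good"),
         (0.75, "reasonably_good"), (0.751, "excellent"), (0.99, "excellent")],
    )
    def test_interpretation_bands(self, value, band):
        assert interpret_ccc(value) == band


class TestBlandAltman:
    def test_zero_differences(self):
        res = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.bias == 0 and res.loa_low == 0 and res.loa_high == 0

    def test_textbook_limits(self):
        res = bland_altman([0.0, 0.0, 0.0], [-2.0, 0.0, 2.0])
        assert res.bias == pytest.approx(0.0)
        assert res.loa_high == pytest.approx(3.92)
        assert res.loa_low == pytest.approx(-3.92)

    def test_recovers_generated_difference_sd(self, rng):
        ref = rng.normal(500, 100, size=2000)
        comp = ref + rng.normal(5, 12, size=2000)
        res = bland_altman(ref, comp)
        assert res.sd_diff == pytest.approx(12, rel=0.1)
        assert res.bias == pytest.approx(5, abs=1.0)

    def test_limits_contain_nominal_mass_on_gaussian_panel(self, rng):
        ref = rng.normal(500, 100, size=5000)
        comp = ref + rng.normal(0, 20, size=5000)
        res = bland_altman(ref, comp)
        inside = (res.differences >= res.loa_low) & (res.differences <= res.loa_high)
        assert inside.mean() >= 0.90

    def test_repeated_measures_correction_widens_with_subject_bias(self, rng):
        subjects = np.repeat(np.arange(30), 4)
        subject_bias = np.repeat(rng.normal(0, 30, size=30), 4)
        ref = rng.normal(500, 80, size=120)
        comp = ref + subject_bias + rng.normal(0, 5, size=120)
        plain = bland_altman(ref, comp)
        corrected = bland_altman(ref, comp, subjects=subjects, repeated_correction=True)
        assert corrected.sd_diff == pytest.approx(plain.sd_diff, rel=0.25)

    def test_single_pair_rejected(self):
        with pytest.raises(InsufficientDataError):
            bland_altman([1.0], [2.0])


class TestKappa:
    def test_identical_labels(self):
        labels = [0, 1, 0, 1, 1, 0]
        assert cohen_kappa(labels, labels).estimate == pytest.approx(1.0)

    def test_hand_computed_two_by_two(self):
        # table a=40, b=10, c=10, d=40 -> p_obs 0.8, p_exp 0.5, kappa 0.6
        ref = [1] * 50 + [0] * 50
        comp = [1] * 40 + [0] * 10 + [1] * 10 + [0] * 40
        res = cohen_kappa(ref, comp)
        assert res.estimate == pytest.approx(0.6)
        assert res.ci_low < 0.6 < res.ci_high

    def test_independent_labels_near_zero(self, rng):
        ref = rng.integers(0, 2, size=10_000)
        comp = rng.integers(0, 2, size=10_000)
        assert abs(cohen_kappa(ref, comp).estimate) < 0.05

    def test_degenerate_marginals_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            cohen_kappa([1, 1, 1], [1, 1, 1])


class TestWeightedKappa:
    def test_perfect_agreement(self):
        cats = [0, 1, 2, 3, 4, 5, 2, 1]
        assert weighted_kappa(cats, cats, n_boot=0).estimate == pytest.approx(1.0)

    def test_maximal_disagreement_is_below_chance(self):
        ref = [0] * 20 + [5] * 20
        comp = [5] * 20 + [0] * 20
        assert weighted_kappa(ref, comp, n_boot=0).estimate < 0

    def test_matches_double_sum_oracle_on_fixed_table(self):
        # 3x3 table laid out explicitly, categories {0,1,2}
        table = np.array([[20, 5, 1], [4, 15, 6], [2, 3, 12]])
        ref, comp = [], []
        for i in range(3):
            for j in range(3):
                ref += [i] * table[i, j]
                comp += [j] * table[i, j]
        res = weighted_kappa(ref, comp, n_categories=3, n_boot=0)
        assert res.estimate == pytest.approx(kappa_oracle(table, linear_weights(3)), abs=1e-12)

    def test_identity_weights_reduce_to_unweighted_kappa(self):
        table = np.array([[20, 5, 1], [4, 15, 6], [2, 3, 12]])
        ref, comp = [], []
        for i in range(3):
            for j in range(3):
                ref += [i] * table[i, j]
                comp += [j] * table[i, j]
        res = weighted_kappa(ref, comp, n_categories=3, weights="identity", n_boot=0)
        assert res.estimate == pytest.approx(kappa_oracle(table), abs=1e-12)

    def test_counts_capped_into_five_plus(self):
        ref = [7, 9, 2]
        comp = [5, 6, 2]
        assert weighted_kappa(ref, comp, n_boot=0).estimate == pytest.approx(1.0)

    def test_bootstrap_ci_reproducible(self, rng):
        ref = rng.integers(0, 4, size=200)
        comp = np.clip(ref + rng.integers(-1, 2, size=200), 0, 5)
        a = weighted_kappa(ref, comp, n_boot=100, seed=7)
        b = weighted_kappa(ref, comp, n_boot=100, seed=7)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        assert a.ci_low <= a.estimate <= a.ci_high


class TestTwoProportion:
    def test_identical_tables_give_zero(self):
        stat, p = two_proportion_test(30, 100, 30, 100)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_textbook_pearson_formula(self):
        stat, _ = two_proportion_test(50, 100, 30, 100)
        expected = pearson_chi2_oracle(np.array([[50, 50], [30, 70]]))
        assert stat == pytest.approx(expected, abs=1e-10)

    def test_zero_expected_cell_undefined(self):
        with pytest.raises(UndefinedStatisticError, match="continuity"):
            two_proportion_test(0, 10, 0, 10)


class TestMeanDifference:
    def test_zero_for_identical(self, rng):
        vals = rng.normal(500, 50, size=40)
        subjects = np.repeat(np.arange(10), 4)
        est, lo, hi = mean_difference_ci(vals, vals, subjects, n_boot=100, seed=3)
        assert est == 0 and lo == 0 and hi == 0

    def test_ci_brackets_known_shift(self, rng):
        ref = rng.normal(500, 50, size=200)
        comp = ref + 25 + rng.normal(0, 5, size=200)
        subjects = np.repeat(np.arange(50), 4)
        est, lo, hi = mean_difference_ci(ref, comp, subjects, n_boot=300, seed=4)
        assert lo < 25 < hi
        assert est == pytest.approx(25, abs=2)


def toy_summaries(rng, n_subjects=12, n_days=4, rules=("fixed30", "choi")):
    """Diary rows plus per-rule rows derived from them with known distortions."""
    rows = []
    for i in range(n_subjects):
        for d in range(1, n_days + 1):
            wear = float(rng.integers(600, 800))
            mvpa = float(rng.integers(30, 90))
            sed = wear * 0.6
            light = wear - sed - mvpa
            base = dict(subject_id=f"S{i:03d}", day=d)
            rows.append(
                base
                | dict(rule="diary", wear_min=wear, sedentary_min=sed, light_min=light,
                       moderate_min=mvpa, vigorous_min=0.0, mvpa_min=mvpa,
                       nonwear_period_count=int(rng.integers(0, 3)))
            )
    df = pd.DataFrame(rows)
    out = [df]
    for rule in rules:
        dup = df.copy()
        dup["rule"] = rule
        out.append(dup)
    return pd.concat(out, ignore_index=True)


class TestReportBuilder:
    def test_self_agreement_is_perfect(self, rng):
        summaries = toy_summaries(rng)
        tables = build_comparison_tables(summaries, seed=0, n_boot=20)
        assert np.allclose(tables["table3_ccc"]["ccc"], 1.0)
        assert np.allclose(tables["table4_mvpa_kappa"]["kappa"].dropna(), 1.0)
        assert np.allclose(tables["table5_periods"]["weighted_kappa"].dropna(), 1.0)
        means = tables["table2_means"].set_index("rule")
        for rule in ("fixed30", "choi"):
            for m in ("wear", "sedentary", "mvpa"):
                assert means.loc[rule, f"{m}_diff"] == 0
        assert np.allclose(tables["fig2_validdays"]["chi2"].dropna(), 0.0)

    def test_report_is_deterministic(self, rng):
        summaries = toy_summaries(rng)
        a = build_comparison_tables(summaries, seed=5, n_boot=50)
        b = build_comparison_tables(summaries, seed=5, n_boot=50)
        for key in a:
            pd.testing.assert_frame_equal(a[key], b[key])

    def test_missing_diary_rejected(self, rng):
        summaries = toy_summaries(rng)
        with pytest.raises(ValueError, match="diary"):
            build_comparison_tables(summaries[summaries["rule"] != "diary"])

    def test_misaligned_rule_rejected(self, rng):
        summaries = toy_summaries(rng)
        broken = summaries.drop(summaries[summaries["rule"] == "choi"].index[:2])
        with pytest.raises(ValueError, match="misaligned"):
            build_comparison_tables(broken)


class TestBootstrapCoverage:
    def test_subject_bootstrap_ci_covers_true_ccc(self, rng):
        """Percentile-bootstrap coverage on 120 simulated panels (the larger
        500-panel study runs in the acceptance suite)."""
        target = true_ccc()
        hits = 0
        trials = 120
        for _ in range(trials):
            ref, comp = simulate_panel(rng, n=20, k=4)
            res = ccc_repeated(panel_from_matrix(ref, comp), n_boot=300, seed=rng.integers(2**31))
            hits += res.ci_low <= target <= res.ci_high
        assert hits / trials >= 0.85
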