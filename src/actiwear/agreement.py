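"""Agreement battery for comparing algorithm wear time with the log diary.

The central statistic is a concordance correlation coefficient (CCC) for
repeated measures: each subject contributes several recording days measured
by both methods (diary reference vs algorithm), and agreement must credit
subject-level and day-level signal shared by the two methods while charging
method bias and method-discordant noise.  The two-method model is

    Y_ijk = mu + s_i + m_j + d_k + (sm)_ij + (sd)_ik + e_ijk

with subject i, method j (2 levels), day k; subject and the interactions
random, method fixed.  Variance shared between methods at the same
subject-day is sigma2_s + sigma2_sd; discordant variance is
sigma2_sm + sigma2_e plus the squared systematic method shift:

    CCC = (s2_s + s2_sd) / (s2_s + s2_sd + s2_sm + s2_e + Delta^2 / 2)

Components are estimated by ANOVA method of moments (negative estimates
truncated at zero); with a single day per subject the estimator collapses to
Lin's classical single-measure CCC.  Confidence intervals come from a
subject-level nonparametric bootstrap.

Also here: Bland-Altman bias and 95% limits of agreement, Cohen's kappa
(binary, for MVPA-guideline days), weighted Cohen's kappa (ordinal, for
non-wear-period counts capped at "5+"), a Pearson chi-square comparison of
valid-day proportions, and the builder that assembles the full per-rule
comparison report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import cohen_kappa_score

DEFAULT_N_BOOT = 1000
CCC_LOW_MAX = 0.45
CCC_GOOD_MAX = 0.75


class InsufficientDataError(ValueError):
    """Too few subjects or pairs to evaluate the statistic."""


class UndefinedStatisticError(ValueError):
    """The statistic is undefined for this input (degenerate variance/marginals)."""


def interpret_ccc(value: float) -> str:
    """Interpretation band: < 0.45 low; 0.45-0.75 reasonably good; > 0.75 excellent."""
    if value < CCC_LOW_MAX:
        return "low"
    if value <= CCC_GOOD_MAX:
        return "reasonably_good"
    return "excellent"


@dataclass
class PairedPanel:
    """Long-form panel of (subject, day) pairs with reference (diary) and
    comparator (algorithm) values aligned one-to-one."""

    subjects: np.ndarray
    days: np.ndarray
    reference: np.ndarray
    comparator: np.ndarray

    def __post_init__(self) -> None:
        self.subjects = np.asarray(self.subjects)
        self.days = np.asarray(self.days)
        self.reference = np.asarray(self.reference, dtype=float)
        self.comparator = np.asarray(self.comparator, dtype=float)
        n = len(self.subjects)
        if not (len(self.days) == len(self.reference) == len(self.comparator) == n):
            raise ValueError("panel columns must have equal length")
        keys = list(zip(self.subjects.tolist(), self.days.tolist()))
        if len(set(keys)) != n:
            raise ValueError("duplicate (subject, day) pair in panel")

    @property
    def n_pairs(self) -> int:
        return len(self.reference)

    @property
    def n_subjects(self) -> int:
        return len(np.unique(self.subjects))

    @property
    def balanced(self) -> bool:
        counts = pd.Series(self.subjects).value_counts()
        return counts.nunique() == 1

    def cell_array(self) -> tuple[np.ndarray, np.ndarray]:
        """Panel as a ``(n_subjects, n_days, 2)`` array with NaN for missing
        subject-days; axis 2 is (reference, comparator).  Subjects with no
        complete pair are dropped with a warning."""
        complete = np.isfinite(self.reference) & np.isfinite(self.comparator)
        if not complete.all():
            dropped = np.unique(self.subjects[~complete])
            kept = np.unique(self.subjects[complete])
            gone = sorted(set(dropped.tolist()) - set(kept.tolist()))
            if gone:
                warnings.warn(f"subjects with no complete pair dropped: {gone}", stacklevel=2)
        subjects = np.unique(self.subjects[complete])
        days = np.unique(self.days[complete])
        if len(subjects) == 0:
            raise InsufficientDataError("no complete (subject, day) pairs")
        y = np.full((len(subjects), len(days), 2), np.nan)
        s_idx = {s: i for i, s in enumerate(subjects.tolist())}
        d_idx = {d: i for i, d in enumerate(days.tolist())}
        for s, d, r, c, ok in zip(
            self.subjects.tolist(),
            self.days.tolist(),
            self.reference,
            self.comparator,
            complete,
        ):
            if ok:
                y[s_idx[s], d_idx[d]] = (r, c)
        return y, subjects


@dataclass
class CCCResult:
    estimate: float
    ci_low: float
    ci_high: float
    interpretation: str
    n_subjects: int
    n_pairs: int
    components: dict = field(default_factory=dict)


def _ccc_from_cells(y: np.ndarray) -> np.ndarray:
    """Method-of-moments CCC on ``(..., n_subjects, n_days, 2)`` cell arrays.

    NaN marks missing subject-days (missing jointly for both methods).
    Batched over leading axes so the bootstrap is a single vectorized call.
    Returns NaN where the denominator is zero.
    """
    m = 2
    n = y.shape[-3]
    present = np.isfinite(y[..., 0])  # (..., n, k)
    kj = present.sum(axis=-1)  # days per subject
    kh = n / np.sum(1.0 / np.maximum(kj, 1), axis=-1)  # harmonic-mean days

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # empty-slice nanmeans
        cell_sm = np.nanmean(y, axis=-2)  # (..., n, 2) subject x method
        cell_sd = np.nanmean(y, axis=-1)  # (..., n, k) subject x day
        daym = np.nanmean(cell_sd, axis=-2)  # (..., k)
    subj = cell_sm.mean(axis=-1)  # (..., n)
    meth = cell_sm.mean(axis=-2)  # (..., 2)
    grand = subj.mean(axis=-1)  # (...)
    delta = meth[..., 0] - meth[..., 1]

    g = grand[..., None]
    ms_s = m * kh * np.sum((subj - g) ** 2, axis=-1) / (n - 1)
    inter_sm = cell_sm - subj[..., None] - meth[..., None, :] + grand[..., None, None]
    ms_sm = kh * np.sum(inter_sm**2, axis=(-2, -1)) / (n - 1)

    df_sd = kj.sum(axis=-1) - n - present.any(axis=-2).sum(axis=-1) + 1
    df_e = np.sum(kj - 1, axis=-1)  # (m-1) = 1
    inter_sd = cell_sd - subj[..., None] - daym[..., None, :] + grand[..., None, None]
    ss_sd = np.nansum(inter_sd**2, axis=(-2, -1))
    ms_sd = np.where(df_sd > 0, m * ss_sd / np.maximum(df_sd, 1), 0.0)
    resid = y - cell_sm[..., None, :] - cell_sd[..., None] + subj[..., None, None]
    ss_e = np.nansum(resid**2, axis=(-3, -2, -1))
    ms_e = np.where(df_e > 0, ss_e / np.maximum(df_e, 1), 0.0)

    s2_e = ms_e
    s2_sm = np.clip((ms_sm - ms_e) / kh, 0.0, None)
    s2_sd = np.clip((ms_sd - ms_e) / m, 0.0, None)
    s2_s = np.clip((ms_s - ms_sm - ms_sd + ms_e) / (m * kh), 0.0, None)

    num = s2_s + s2_sd
    den = num + s2_sm + s2_e + 0.5 * delta**2
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def ccc_repeated(
    panel: PairedPanel,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | np.random.SeedSequence | None = None,
    ci_level: float = 0.95,
) -> CCCResult:
    """Repeated-measures concordance correlation coefficient with a
    subject-level bootstrap confidence interval.

    Raises :class:`InsufficientDataError` for fewer than 2 subjects and
    :class:`UndefinedStatisticError` when total variance is zero.
    """
    y, subjects = panel.cell_array()
    n = len(subjects)
    if n < 2:
        raise InsufficientDataError("CCC requires at least 2 subjects")
    estimate = float(_ccc_from_cells(y))
    if not np.isfinite(estimate):
        raise UndefinedStatisticError("CCC undefined: zero total variance")

    ci_low = ci_high = estimate
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        boot = _ccc_from_cells(y[idx])
        alpha = 100 * (1 - ci_level) / 2
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ci_low = float(np.nanpercentile(boot, alpha))
            ci_high = float(np.nanpercentile(boot, 100 - alpha))
        ci_low = min(ci_low, estimate)
        ci_high = max(ci_high, estimate)
    return CCCResult(
        estimate=estimate,
        ci_low=ci_low,
        ci_high=ci_high,
        interpretation=interpret_ccc(estimate),
        n_subjects=n,
        n_pairs=int(np.isfinite(y[..., 0]).sum()),
    )


def lin_ccc(x, y) -> float:
    """Lin's classical single-measure CCC: 2*cov / (var_x + var_y + (mx-my)^2).

    Sample moments use the n-1 denominator, matching the repeated-measures
    estimator's single-day reduction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise InsufficientDataError("need >= 2 aligned pairs")
    sxy = np.cov(x, y, ddof=1)[0, 1]
    den = np.var(x, ddof=1) + np.var(y, ddof=1) + (x.mean() - y.mean()) ** 2
    if den == 0:
        raise UndefinedStatisticError("zero total variance")
    return float(2 * sxy / den)


@dataclass
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    means: np.ndarray
    differences: np.ndarray


def bland_altman(
    reference,
    comparator,
    subjects=None,
    repeated_correction: bool = False,
) -> BlandAltmanResult:
    """Bland-Altman agreement: bias = mean(comparator - reference) and 95%
    limits of agreement bias +/- 1.96 * SD of the differences.

    By default subject-days are treated as independent pairs (the plots pool
    all days).  With ``repeated_correction=True`` and ``subjects`` given, the
    SD is rebuilt from a one-way ANOVA of differences by subject so that
    within- and between-subject spread both enter the limits.
    """
    reference = np.asarray(reference, dtype=float)
    comparator = np.asarray(comparator, dtype=float)
    if len(reference) != len(comparator) or len(reference) < 2:
        raise InsufficientDataError("need >= 2 pairs")
    diffs = comparator - reference
    means = (comparator + reference) / 2.0
    bias = float(diffs.mean())
    if repeated_correction:
        if subjects is None:
            raise ValueError("repeated_correction requires subject ids")
        sd = _repeated_sd(diffs, np.asarray(subjects))
    else:
        sd = float(np.std(diffs, ddof=1))
    return BlandAltmanResult(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        sd_diff=sd,
        means=means,
        differences=diffs,
    )


def _repeated_sd(diffs: np.ndarray, subjects: np.ndarray) -> float:
    # One-way ANOVA on differences by subject: total SD^2 = between-subject
    # component + within-subject mean square.
    groups = pd.Series(diffs).groupby(pd.Series(subjects))
    n_i = groups.count().to_numpy(dtype=float)
    if (n_i <= 1).all():
        return float(np.std(diffs, ddof=1))
    grand = diffs.mean()
    means_i = groups.mean().to_numpy()
    ss_b = float(np.sum(n_i * (means_i - grand) ** 2))
    ss_w = float(np.sum((diffs - groups.transform("mean").to_numpy()) ** 2))
    g = len(n_i)
    ms_b = ss_b / (g - 1)
    ms_w = ss_w / max(len(diffs) - g, 1)
    n0 = (len(diffs) - np.sum(n_i**2) / len(diffs)) / (g - 1)
    var_b = max((ms_b - ms_w) / n0, 0.0)
    return float(np.sqrt(var_b + ms_w))


@dataclass
class KappaResult:
    estimate: float
    ci_low: float
    ci_high: float
    n: int


def cohen_kappa(ref_labels, comp_labels, ci_level: float = 0.95) -> KappaResult:
    """Cohen's kappa on binary labels with an asymptotic confidence interval."""
    ref = np.asarray(ref_labels).astype(int)
    comp = np.asarray(comp_labels).astype(int)
    if len(ref) != len(comp) or len(ref) == 0:
        raise InsufficientDataError("label sequences must align and be non-empty")
    n = len(ref)
    p_ref = np.array([(ref == 0).mean(), (ref == 1).mean()])
    p_comp = np.array([(comp == 0).mean(), (comp == 1).mean()])
    p_exp = float(p_ref @ p_comp)
    if p_exp >= 1.0:
        raise UndefinedStatisticError("kappa undefined: degenerate marginals (p_exp = 1)")
    kappa = float(cohen_kappa_score(ref, comp, labels=[0, 1]))
    p_obs = float((ref == comp).mean())
    se = np.sqrt(p_obs * (1 - p_obs) / (n * (1 - p_exp) ** 2))
    z = stats.norm.ppf(0.5 + ci_level / 2)
    return KappaResult(
        estimate=kappa,
        ci_low=float(np.clip(kappa - z * se, -1, 1)),
        ci_high=float(np.clip(kappa + z * se, -1, 1)),
        n=n,
    )


def cap_categories(values, cap: int = 5) -> np.ndarray:
    """Map ordinal counts onto categories {0, 1, ..., cap} with the top
    category absorbing everything >= cap ("5 or more")."""
    return np.minimum(np.asarray(values).astype(int), cap)


def weighted_kappa(
    ref_cats,
    comp_cats,
    n_categories: int = 6,
    weights: str = "linear",
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | np.random.SeedSequence | None = None,
    ci_level: float = 0.95,
) -> KappaResult:
    """Weighted Cohen's kappa for ordinal categories, w_ij = 1 - |i-j|/(k-1)
    (``weights="quadratic"`` available), with a pair-bootstrap CI."""
    ref = cap_categories(ref_cats, n_categories - 1)
    comp = cap_categories(comp_cats, n_categories - 1)
    if len(ref) != len(comp) or len(ref) == 0:
        raise InsufficientDataError("category sequences must align and be non-empty")
    if np.any(ref < 0) or np.any(comp < 0):
        raise ValueError("categories must be non-negative")
    labels = np.arange(n_categories)
    if len(np.unique(ref)) == 1 and np.array_equal(np.unique(ref), np.unique(comp)):
        raise UndefinedStatisticError("kappa undefined: degenerate marginals")
    sk_weights = {"linear": "linear", "quadratic": "quadratic", "identity": None}[weights]
    kappa = float(cohen_kappa_score(ref, comp, labels=labels, weights=sk_weights))
    ci_low = ci_high = kappa
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n = len(ref)
        boot = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            rb, cb = ref[idx], comp[idx]
            if len(np.unique(rb)) == 1 and np.array_equal(np.unique(rb), np.unique(cb)):
                boot[b] = np.nan
                continue
            boot[b] = cohen_kappa_score(rb, cb, labels=labels, weights=sk_weights)
        alpha = 100 * (1 - ci_level) / 2
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ci_low = min(float(np.nanpercentile(boot, alpha)), kappa)
            ci_high = max(float(np.nanpercentile(boot, 100 - alpha)), kappa)
    return KappaResult(estimate=kappa, ci_low=ci_low, ci_high=ci_high, n=len(ref))


def two_proportion_test(
    n_valid_ref: int, n_total_ref: int, n_valid_comp: int, n_total_comp: int
) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on the 2x2 table of
    valid/invalid days by method."""
    if n_total_ref <= 0 or n_total_comp <= 0:
        raise InsufficientDataError("totals must be positive")
    table = np.array(
        [
            [n_valid_ref, n_total_ref - n_valid_ref],
            [n_valid_comp, n_total_comp - n_valid_comp],
        ]
    )
    if np.any(table < 0):
        raise ValueError("counts exceed totals")
    expected = stats.contingency.expected_freq(table) if table.sum() else None
    if expected is None or np.any(expected == 0):
        raise UndefinedStatisticError(
            "chi-square undefined: zero expected cell; consider an exact or "
            "continuity-corrected test"
        )
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def mean_difference_ci(
    reference,
    comparator,
    subjects,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | np.random.SeedSequence | None = None,
    ci_level: float = 0.95,
) -> tuple[float, float, float]:
    """Mean (comparator - reference) over subject-days with a subject-level
    bootstrap confidence interval."""
    diffs = np.asarray(comparator, dtype=float) - np.asarray(reference, dtype=float)
    subjects = np.asarray(subjects)
    uniq = np.unique(subjects)
    groups = [diffs[subjects == s] for s in uniq]
    estimate = float(diffs.mean())
    if n_boot <= 0 or len(uniq) < 2:
        return estimate, estimate, estimate
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, len(uniq), size=len(uniq))
        boot[b] = np.concatenate([groups[i] for i in idx]).mean()
    alpha = 100 * (1 - ci_level) / 2
    return (
        estimate,
        float(np.percentile(boot, alpha)),
        float(np.percentile(boot, 100 - alpha)),
    )


# ---------------------------------------------------------------------------
# Report bundle
# ---------------------------------------------------------------------------

MEASURES = {"wear": "wear_min", "sedentary": "sedentary_min", "mvpa": "mvpa_min"}
DIARY_RULE = "diary"


def _aligned(summaries: pd.DataFrame, rule: str, diary: pd.DataFrame) -> pd.DataFrame:
    sub = summaries[summaries["rule"] == rule]
    if sub.empty:
        raise ValueError(f"no summaries for rule {rule!r}")
    merged = diary.merge(sub, on=["subject_id", "day"], suffixes=("_ref", "_cmp"))
    if len(merged) != len(diary):
        raise ValueError(f"rule {rule!r} is misaligned with the diary subject-days")
    return merged


def build_comparison_tables(
    summaries: pd.DataFrame,
    rules: list[str] | None = None,
    seed: int = 0,
    n_boot: int = DEFAULT_N_BOOT,
    min_wear_hours: float = 10,
    mvpa_threshold_min: float = 60,
) -> dict[str, pd.DataFrame]:
    """Assemble the full diary-vs-algorithm comparison report.

    ``summaries`` is the long day-summary table (one row per subject-day and
    rule, diary rows labelled ``"diary"``).  Returns one DataFrame per report
    artifact: per-rule means and mean differences with subject-bootstrap CIs,
    the CCC table for wear/sedentary/MVPA, MVPA-guideline day counts with
    kappas, the non-wear-period-count distribution with weighted kappas,
    valid-day percentages with chi-square, and Bland-Altman plot data.
    Deterministic for a fixed ``seed``.
    """
    diary = summaries[summaries["rule"] == DIARY_RULE]
    if diary.empty:
        raise ValueError("summaries must include diary reference rows")
    if rules is None:
        rules = [r for r in summaries["rule"].unique() if r != DIARY_RULE]
    seeds = iter(np.random.SeedSequence(seed).spawn(len(rules) * 8 + 8))

    means_rows = []
    ccc_rows = []
    mvpa_rows = []
    period_rows = []
    valid_rows = []
    ba_rows = []
    ba_summary_rows = []

    def describe(df: pd.DataFrame, rule: str) -> dict:
        row = {"rule": rule, "n_days": len(df)}
        for name, col in MEASURES.items():
            row[f"{name}_mean"] = df[col].mean()
            row[f"{name}_sd"] = df[col].std(ddof=1)
        return row

    means_rows.append(describe(diary, DIARY_RULE))
    diary_valid = int((diary["wear_min"] >= min_wear_hours * 60).sum())
    diary_guideline = (diary["mvpa_min"] >= mvpa_threshold_min).astype(int)
    valid_rows.append(
        {
            "rule": DIARY_RULE,
            "n_valid_days": diary_valid,
            "n_days": len(diary),
            "pct_valid": 100 * diary_valid / len(diary),
            "chi2": np.nan,
            "p_value": np.nan,
        }
    )
    mvpa_rows.append(
        {"rule": DIARY_RULE, "n_guideline_days": int(diary_guideline.sum())}
        | dict.fromkeys(("kappa", "kappa_ci_low", "kappa_ci_high"), np.nan)
    )
    period_rows.append(_period_row(diary, DIARY_RULE))

    for rule in rules:
        merged = _aligned(summaries, rule, diary)
        cmp_df = summaries[summaries["rule"] == rule]
        row = describe(cmp_df, rule)
        for name, col in MEASURES.items():
            est, lo, hi = mean_difference_ci(
                merged[f"{col}_ref"],
                merged[f"{col}_cmp"],
                merged["subject_id"],
                n_boot=n_boot,
                seed=next(seeds),
            )
            row[f"{name}_diff"] = est
            row[f"{name}_diff_ci_low"] = lo
            row[f"{name}_diff_ci_high"] = hi
        means_rows.append(row)

        for name, col in MEASURES.items():
            panel = PairedPanel(
                subjects=merged["subject_id"].to_numpy(),
                days=merged["day"].to_numpy(),
                reference=merged[f"{col}_ref"].to_numpy(),
                comparator=merged[f"{col}_cmp"].to_numpy(),
            )
            res = ccc_repeated(panel, n_boot=n_boot, seed=next(seeds))
            ccc_rows.append(
                {
                    "rule": rule,
                    "measure": name,
                    "ccc": res.estimate,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "interpretation": res.interpretation,
                }
            )

        ref_g = (merged["mvpa_min_ref"] >= mvpa_threshold_min).astype(int)
        cmp_g = (merged["mvpa_min_cmp"] >= mvpa_threshold_min).astype(int)
        try:
            kap = cohen_kappa(ref_g, cmp_g)
            kap_vals = (kap.estimate, kap.ci_low, kap.ci_high)
        except UndefinedStatisticError:
            kap_vals = (np.nan, np.nan, np.nan)
        mvpa_rows.append(
            {
                "rule": rule,
                "n_guideline_days": int(cmp_g.sum()),
                "kappa": kap_vals[0],
                "kappa_ci_low": kap_vals[1],
                "kappa_ci_high": kap_vals[2],
            }
        )

        prow = _period_row(cmp_df, rule)
        try:
            wk = weighted_kappa(
                merged["nonwear_period_count_ref"],
                merged["nonwear_period_count_cmp"],
                n_boot=n_boot,
                seed=next(seeds),
            )
            prow |= {
                "weighted_kappa": wk.estimate,
                "wk_ci_low": wk.ci_low,
                "wk_ci_high": wk.ci_high,
            }
        except UndefinedStatisticError:
            prow |= dict.fromkeys(("weighted_kappa", "wk_ci_low", "wk_ci_high"), np.nan)
        period_rows.append(prow)

        cmp_valid = int((cmp_df["wear_min"] >= min_wear_hours * 60).sum())
        try:
            chi2, p = two_proportion_test(diary_valid, len(diary), cmp_valid, len(cmp_df))
        except UndefinedStatisticError:
            chi2, p = np.nan, np.nan
        valid_rows.append(
            {
                "rule": rule,
                "n_valid_days": cmp_valid,
                "n_days": len(cmp_df),
                "pct_valid": 100 * cmp_valid / len(cmp_df),
                "chi2": chi2,
                "p_value": p,
            }
        )

        ba = bland_altman(merged["sedentary_min_ref"], merged["sedentary_min_cmp"])
        ba_summary_rows.append(
            {
                "rule": rule,
                "bias": ba.bias,
                "loa_low": ba.loa_low,
                "loa_high": ba.loa_high,
                "sd_diff": ba.sd_diff,
            }
        )
        ba_rows.append(
            pd.DataFrame(
                {
                    "rule": rule,
                    "subject_id": merged["subject_id"],
                    "day": merged["day"],
                    "pair_mean": ba.means,
                    "difference": ba.differences,
                }
            )
        )

    return {
        "table2_means": pd.DataFrame(means_rows),
        "table3_ccc": pd.DataFrame(ccc_rows),
        "table4_mvpa_kappa": pd.DataFrame(mvpa_rows),
        "table5_periods": pd.DataFrame(period_rows),
        "fig2_validdays": pd.DataFrame(valid_rows),
        "fig1_bland_altman": pd.concat(ba_rows, ignore_index=True)
        if ba_rows
        else pd.DataFrame(),
        "fig1_bland_altman_summary": pd.DataFrame(ba_summary_rows),
    }


def _period_row(df: pd.DataFrame, rule: str) -> dict:
    cats = cap_categories(df["nonwear_period_count"].to_numpy())
    freq = np.bincount(cats, minlength=6) / len(cats) * 100
    raw = df["nonwear_period_count"].to_numpy()
    return {
        "rule": rule,
        **{f"pct_{i}": freq[i] for i in range(5)},
        "pct_5plus": freq[5],
        "range_min": int(raw.min()),
        "range_max": int(raw.max()),
    }


def plot_bland_altman(result: BlandAltmanResult, ax=None, title: str = ""):
    """Convenience scatter of pair means vs differences with bias and limits."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(result.means, result.differences, s=12, alpha=0.6)
    for yline, style in ((result.bias, "-"), (result.loa_low, "--"), (result.loa_high, "--")):
        ax.axhline(yline, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel("Mean of methods (min/day)")
    ax.set_ylabel("Algorithm - diary (min/day)")
    if title:
        ax.set_title(title)
    return ax
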