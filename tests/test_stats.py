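import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ggnquant.errors import DegenerateSampleError, SeparationError
from ggnquant.stats import (
    ThresholdRule,
    anova_with_posthoc,
    apply_rule,
    bonferroni,
    evaluate_rule,
    icc_two_observers,
    roc_auc,
    spearman_vs_invasion,
    stepwise_logistic,
    vif_screen,
)


def _table(groups: dict[str, np.ndarray], feature="f") -> pd.DataFrame:
    rows = []
    for g, vals in groups.items():
        rows += [{"class_label": g, feature: float(v)} for v in vals]
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------- ANOVA


def test_identical_groups_give_f_zero_p_one():
    g = np.array([1.0, 2.0, 3.0, 4.0])
    row = anova_with_posthoc(_table({"AIS": g, "MIA": g, "INV": g}), "f")
    assert row.f_statistic == pytest.approx(0.0, abs=1e-12)
    assert row.p_raw == pytest.approx(1.0)


def test_family_correction_multiplies_and_caps():
    assert bonferroni(0.01, 7) == pytest.approx(0.07)
    assert bonferroni(0.4, 7) == 1.0
    g = np.array([1.0, 2.0, 3.0, 4.0])
    row = anova_with_posthoc(_table({"AIS": g, "MIA": g + 0.5, "INV": g + 1}), "f",
                             family_size=7)
    assert row.p_corrected == pytest.approx(min(1.0, row.p_raw * 7))
    assert row.p_corrected >= row.p_raw


def test_widely_separated_groups_are_detected():
    rng = np.random.default_rng(0)
    row = anova_with_posthoc(
        _table({
            "AIS": rng.normal(0, 1, 30),
            "MIA": rng.normal(10, 1, 30),
            "INV": rng.normal(20, 1, 30),
        }),
        "f",
    )
    assert row.p_raw < 1e-6
    assert row.pairwise_p[("AIS", "INV")] < 1e-6


def test_anova_rejects_degenerate_groups():
    with pytest.raises(DegenerateSampleError):
        anova_with_posthoc(
            _table({"AIS": [1.0, 1.0], "MIA": [2.0, 2.0], "INV": [3.0, 3.0]}), "f"
        )


# -------------------------------------------------------------------- Spearman


def test_spearman_extremes_and_oracle():
    df = pd.DataFrame({"f": [1.0, 2, 3, 4, 5], "invasion_extent_mm": [2.0, 4, 6, 8, 10]})
    rho, _ = spearman_vs_invasion(df, "f")
    assert rho == pytest.approx(1.0)
    df["f"] = -df["f"]
    rho, _ = spearman_vs_invasion(df, "f")
    assert rho == pytest.approx(-1.0)

    rng = np.random.default_rng(12)
    for _ in range(20):
        n = int(rng.integers(5, 60))
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        df = pd.DataFrame({"f": x, "invasion_extent_mm": y})
        rho, _ = spearman_vs_invasion(df, "f")
        # independent oracle: rank transform then Pearson
        oracle = sps.pearsonr(sps.rankdata(x), sps.rankdata(y))[0]
        assert rho == pytest.approx(oracle, abs=1e-12)


def test_spearman_rejects_constant_input():
    df = pd.DataFrame({"f": [1.0] * 6, "invasion_extent_mm": [1.0, 2, 3, 4, 5, 6]})
    with pytest.raises(DegenerateSampleError):
        spearman_vs_invasion(df, "f")


# ------------------------------------------------------------------------- ICC


def test_identical_observers_have_icc_one():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    icc, (lo, hi) = icc_two_observers(x, x)
    assert icc == pytest.approx(1.0)
    assert lo == hi == 1.0


def test_independent_observers_have_icc_near_zero():
    rng = np.random.default_rng(2)
    icc, _ = icc_two_observers(rng.normal(size=1500), rng.normal(size=1500))
    assert abs(icc) < 0.1


def test_icc_is_symmetric_and_matches_reference_implementation():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(31)
    for _ in range(8):
        n = int(rng.integers(5, 40))
        subject = rng.normal(0, 2, size=n)
        o1 = subject + rng.normal(0, 1, size=n)
        o2 = subject + 0.3 + rng.normal(0, 1, size=n)
        icc, (lo, hi) = icc_two_observers(o1, o2)
        icc_swap, _ = icc_two_observers(o2, o1)
        assert icc == pytest.approx(icc_swap, abs=1e-12)
        long = pd.DataFrame({
            "subject": np.tile(np.arange(n), 2),
            "rater": np.repeat(["a", "b"], n),
            "y": np.concatenate([o1, o2]),
        })
        ref = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="y")
        ref2 = ref.loc[ref["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
        ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
        assert icc == pytest.approx(float(ref2["ICC"]), abs=1e-9)
        # pingouin rounds its CI to two decimals
        assert (lo, hi) == pytest.approx(tuple(ref2[ci_col]), abs=1.5e-2)


def test_icc_needs_five_pairs():
    with pytest.raises(DegenerateSampleError):
        icc_two_observers(np.arange(4.0), np.arange(4.0))


# ------------------------------------------------------------------------- VIF


def test_independent_features_are_all_retained():
    rng = np.random.default_rng(7)
    df = pd.DataFrame(rng.normal(size=(500, 4)), columns=list("abcd"))
    rep = vif_screen(df, list("abcd"))
    assert rep.retained == list("abcd") and rep.removed == []
    assert all(v < 1.1 for v in rep.steps[-1]["vif"].values())


def test_duplicated_column_is_infinitely_inflated_and_removed():
    rng = np.random.default_rng(8)
    df = pd.DataFrame({"a": rng.normal(size=100)})
    df["b"] = df["a"]
    df["c"] = rng.normal(size=100)
    rep = vif_screen(df, ["a", "b", "c"])
    assert len(rep.removed) == 1 and rep.removed[0] in {"a", "b"}
    assert math.isinf(rep.steps[0]["vif"][rep.removed[0]])


def test_near_linear_combination_is_flagged_and_vif_matches_oracle():
    rng = np.random.default_rng(9)
    a = rng.normal(size=300)
    b = rng.normal(size=300)
    df = pd.DataFrame({"a": a, "b": b, "s": a + b + rng.normal(0, 0.05, 300)})
    rep = vif_screen(df, ["a", "b", "s"], threshold=10)
    assert rep.removed  # one of the collinear trio must go
    # oracle: statsmodels VIF on the pre-removal design
    from statsmodels.stats.outliers_influence import variance_inflation_factor
    import statsmodels.api as sm

    X = sm.add_constant(df[["a", "b", "s"]].to_numpy())
    for j, name in enumerate(["a", "b", "s"]):
        ref = variance_inflation_factor(X, j + 1)
        assert rep.steps[0]["vif"][name] == pytest.approx(ref, rel=1e-6)
    assert rep.steps[0]["vif"]["s"] > 10


# ------------------------------------------------------------------- stepwise


def _logit_cohort(rng, n=200, beta=0.0):
    X = rng.normal(size=(n, 5))
    eta = beta * X[:, 0]
    y = rng.random(n) < 1 / (1 + np.exp(-eta))
    df = pd.DataFrame(X, columns=[f"x{i}" for i in range(5)])
    df["class_label"] = np.where(y, "INV", "AIS")
    return df


def test_strong_predictor_is_retained_and_noise_removed():
    rng = np.random.default_rng(10)
    df = _logit_cohort(rng, n=200, beta=1.5)
    model = stepwise_logistic(df, [f"x{i}" for i in range(5)])
    assert "x0" in model.variables
    assert len(model.variables) <= 2  # at most one false positive here
    assert model.odds_ratios["x0"] > 1.0
    lo, hi = model.ci_95["x0"]
    assert lo < model.odds_ratios["x0"] < hi


def test_null_outcome_can_reduce_to_intercept_only():
    rng = np.random.default_rng(11)
    df = _logit_cohort(rng, n=200, beta=0.0)
    model = stepwise_logistic(df, [f"x{i}" for i in range(5)])
    assert len(model.variables) <= 1  # nothing real to keep
    assert model.coefficients["intercept"] == pytest.approx(0.0, abs=0.5)


def test_elimination_never_removes_a_significant_variable():
    rng = np.random.default_rng(13)
    for _ in range(5):
        df = _logit_cohort(rng, n=150, beta=1.0)
        model = stepwise_logistic(df, [f"x{i}" for i in range(5)])
        for step in model.trace:
            if step["removed"] is not None:
                assert step["removal_p"][step["removed"]] > 0.10


def test_perfect_separation_raises():
    x = np.concatenate([np.linspace(-2, -1, 20), np.linspace(1, 2, 20)])
    df = pd.DataFrame({"x0": x, "class_label": np.where(x > 0, "INV", "AIS")})
    with pytest.raises(SeparationError):
        stepwise_logistic(df, ["x0"])


def test_single_class_outcome_rejected():
    df = pd.DataFrame({"x0": [1.0, 2.0, 3.0], "class_label": ["AIS"] * 3})
    with pytest.raises(DegenerateSampleError):
        stepwise_logistic(df, ["x0"])


# ------------------------------------------------------------------------- ROC


def mann_whitney_auc(scores, labels):
    """Brute-force pairwise concordance with half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def test_perfect_separation_gives_auc_one():
    res = roc_auc(np.array([0.1, 0.2, 0.8, 0.9]), np.array([0, 0, 1, 1]), n_boot=50)
    assert res.auc == 1.0


def test_auc_equals_pairwise_concordance_oracle():
    rng = np.random.default_rng(14)
    for _ in range(25):
        n = int(rng.integers(6, 50))
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
        res = roc_auc(scores, labels, n_boot=10)
        assert res.auc == pytest.approx(mann_whitney_auc(scores, labels), abs=1e-12)


def test_auc_is_invariant_under_monotone_transform():
    rng = np.random.default_rng(15)
    scores = rng.normal(size=80)
    labels = rng.integers(0, 2, size=80)
    labels[:2] = [0, 1]
    a = roc_auc(scores, labels, n_boot=10).auc
    b = roc_auc(np.exp(3 * scores) + 7, labels, n_boot=10).auc
    assert a == pytest.approx(b, abs=1e-12)


def test_bootstrap_ci_brackets_the_point_estimate():
    rng = np.random.default_rng(16)
    scores = np.concatenate([rng.normal(0, 1, 100), rng.normal(1, 1, 100)])
    labels = np.array([0] * 100 + [1] * 100)
    res = roc_auc(scores, labels, n_boot=500, seed=3)
    assert res.ci_95[0] <= res.auc <= res.ci_95[1]
    assert res.ci_95[0] > 0.5  # clearly better than chance


def test_single_class_roc_rejected():
    with pytest.raises(DegenerateSampleError):
        roc_auc(np.array([0.1, 0.2]), np.array([1, 1]))


# ------------------------------------------------------------------------ rule


def test_rule_boundary_is_inclusive():
    rule = ThresholdRule()
    assert apply_rule({"p75_hu": -400.0, "entropy_bits": 8.0}, rule) is True
    assert apply_rule({"p75_hu": -500.0, "entropy_bits": 8.5}, rule) is False
    assert apply_rule({"p75_hu": -470.0, "entropy_bits": 7.90}, rule) is True
    assert apply_rule({"p75_hu": -469.9, "entropy_bits": 7.89}, rule) is False


def test_rule_ppv_matches_exhaustive_counting():
    table = pd.DataFrame({
        "p75_hu": [-400, -400, -400, -500, -500, -460],
        "entropy_bits": [8.0, 8.0, 7.5, 8.2, 7.0, 7.9],
        "class_label": ["INV", "AIS", "INV", "INV", "AIS", "INV"],
    })
    ev = evaluate_rule(table)
    # rule-positive rows: 0, 1, 5 -> 2 truly invasive of 3
    assert ev["n_rule_positive"] == 3
    assert ev["true_positive"] == 2
    assert ev["ppv"] == pytest.approx(2 / 3)
    assert ev["sensitivity"] == pytest.approx(2 / 4)
    assert ev["specificity"] == pytest.approx(1 / 2)
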