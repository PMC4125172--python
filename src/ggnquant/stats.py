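"""The inference chain on a per-nodule feature table.

Given one row per nodule (features + class label + invasion extent), this
module reproduces the classical radiomics analysis sequence:

1. one-way ANOVA across the three pathologic classes with Bonferroni-
   corrected overall P and Bonferroni post hoc pairwise comparisons;
2. Spearman correlation of each feature with the invasion extent;
3. two-observer agreement as the two-way random-effects, absolute-
   agreement, single-measure intraclass correlation ICC(2,1);
4. multicollinearity screening by variance inflation factor (VIF), with
   iterative removal of the worst offender above the threshold;
5. backward-stepwise multivariable logistic regression (invasive vs
   AIS/MIA) with likelihood-ratio removal tests at P > 0.10;
6. ROC analysis of model scores, AUC with stratified-bootstrap CI;
7. the two-threshold invasiveness rule: predict invasive when the 75th
   percentile attenuation >= -470 HU AND entropy >= 7.90 bits (inclusive).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.metrics import roc_auc_score, roc_curve

from .errors import DegenerateSampleError, MissingFeatureError, SeparationError

PAIR_NAMES = (("AIS", "MIA"), ("MIA", "INV"), ("AIS", "INV"))


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-corrected P value: min(1, p * m)."""
    return min(1.0, p * m)


# ---------------------------------------------------------------------------
# group comparison


@dataclass(frozen=True)
class AnovaRow:
    feature: str
    f_statistic: float
    p_raw: float
    p_corrected: float  # family-level Bonferroni (x family_size, capped)
    family_size: int
    pairwise_p: dict[tuple[str, str], float]  # Bonferroni x 3, capped


def anova_with_posthoc(
    table: pd.DataFrame,
    feature: str,
    group_col: str = "class_label",
    family_size: int = 1,
    groups: tuple[str, ...] = ("AIS", "MIA", "INV"),
) -> AnovaRow:
    """One-way ANOVA across classes plus Bonferroni post hoc t-tests.

    The overall P is additionally multiplied by ``family_size`` (capped at
    1) to correct across the family of variables the feature belongs to.
    Pairwise comparisons are pooled-variance two-sample t-tests with
    Bonferroni multiplication by the number of pairs.
    """
    if feature not in table.columns:
        raise MissingFeatureError(f"feature {feature!r} not in table")
    samples = []
    for g in groups:
        x = table.loc[table[group_col] == g, feature].dropna().to_numpy(dtype=float)
        if x.size < 2:
            raise DegenerateSampleError(f"group {g} has n < 2 for {feature}")
        samples.append(x)
    if all(np.var(x) == 0 for x in samples):
        raise DegenerateSampleError(f"zero within-group variance everywhere for {feature}")
    f_stat, p_raw = sps.f_oneway(*samples)
    if math.isnan(f_stat):  # all group means equal with zero between-group SS
        f_stat, p_raw = 0.0, 1.0
    pairwise: dict[tuple[str, str], float] = {}
    n_pairs = len(groups) * (len(groups) - 1) // 2
    for (ga, gb) in PAIR_NAMES:
        if ga in groups and gb in groups:
            xa = samples[groups.index(ga)]
            xb = samples[groups.index(gb)]
            _, p = sps.ttest_ind(xa, xb, equal_var=True)
            pairwise[(ga, gb)] = bonferroni(float(p), n_pairs)
    return AnovaRow(
        feature=feature,
        f_statistic=float(f_stat),
        p_raw=float(p_raw),
        p_corrected=bonferroni(float(p_raw), family_size),
        family_size=family_size,
        pairwise_p=pairwise,
    )


def spearman_vs_invasion(
    table: pd.DataFrame, feature: str, extent_col: str = "invasion_extent_mm"
) -> tuple[float, float]:
    """Spearman correlation of a feature with pathologic invasion extent."""
    x = table[feature].to_numpy(dtype=float)
    y = table[extent_col].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 4:
        raise DegenerateSampleError(f"need n >= 4 for Spearman, got {x.size}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateSampleError("constant input: Spearman undefined")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# interobserver agreement


def icc_two_observers(
    obs1: np.ndarray, obs2: np.ndarray, alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Computed from the two-way ANOVA mean squares (subjects x raters) with
    the F-based confidence interval of McGraw & Wong.  Symmetric in the two
    observers.  Requires n >= 5 paired measurements.
    """
    y1 = np.asarray(obs1, dtype=float)
    y2 = np.asarray(obs2, dtype=float)
    if y1.shape != y2.shape or y1.ndim != 1:
        raise DegenerateSampleError("observers must be equal-length 1D arrays")
    ok = np.isfinite(y1) & np.isfinite(y2)
    y1, y2 = y1[ok], y2[ok]
    n = y1.size
    if n < 5:
        raise DegenerateSampleError(f"need n >= 5 pairs for ICC, got {n}")
    k = 2
    Y = np.column_stack([y1, y2])
    grand = Y.mean()
    row_means = Y.mean(axis=1)
    col_means = Y.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((Y - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise DegenerateSampleError("no variance at all: ICC undefined")
    icc = (msr - mse) / denom

    if mse == 0 and msc == 0:  # perfect agreement
        return 1.0, (1.0, 1.0)
    r = icc
    a = k * r / (n * (1 - r)) if r < 1 else np.inf
    b = 1 + k * r * (n - 1) / (n * (1 - r)) if r < 1 else np.inf
    if not np.isfinite(a) or not np.isfinite(b):
        return float(icc), (1.0, 1.0)
    num_v = (a * msc + b * mse) ** 2
    den_v = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num_v / den_v if den_v > 0 else 1.0
    f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    lower = float(np.clip(lower, -1.0, 1.0))
    upper = float(np.clip(upper, -1.0, 1.0))
    return float(icc), (lower, upper)


# ---------------------------------------------------------------------------
# multicollinearity


@dataclass(frozen=True)
class VifReport:
    retained: list[str]
    removed: list[str]
    steps: list[dict]  # per-iteration VIF map + removal decision


def _vif_one(X: np.ndarray, j: int) -> float:
    """VIF of column j: 1 / (1 - R^2) regressing it on the other columns."""
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    design = np.column_stack([np.ones(len(y)), others])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return math.inf
    r2 = 1.0 - ss_res / ss_tot
    if r2 >= 1.0 - 1e-12:
        return math.inf
    return 1.0 / (1.0 - r2)


def vif_screen(
    table: pd.DataFrame, candidate_features: list[str], threshold: float = 10.0
) -> VifReport:
    """Iteratively drop the largest-VIF feature until all VIF <= threshold.

    Perfect collinearity gives VIF = +inf and is removed first.  At least
    one feature is always retained.
    """
    if len(candidate_features) < 2:
        raise DegenerateSampleError("VIF screen needs >= 2 candidate features")
    sub = table[candidate_features].dropna()
    if len(sub) <= len(candidate_features) + 1:
        raise DegenerateSampleError("not enough rows for VIF screening")
    current = list(candidate_features)
    removed: list[str] = []
    steps: list[dict] = []
    while len(current) >= 2:
        X = sub[current].to_numpy(dtype=float)
        vifs = {name: _vif_one(X, j) for j, name in enumerate(current)}
        worst = max(vifs, key=lambda nm: vifs[nm])
        if vifs[worst] > threshold:
            steps.append({"vif": dict(vifs), "removed": worst})
            current.remove(worst)
            removed.append(worst)
        else:
            steps.append({"vif": dict(vifs), "removed": None})
            break
    return VifReport(retained=current, removed=removed, steps=steps)


# ---------------------------------------------------------------------------
# stepwise logistic regression


@dataclass(frozen=True)
class LogisticModel:
    variables: list[str]
    odds_ratios: dict[str, float]
    ci_95: dict[str, tuple[float, float]]  # Wald, on the OR scale
    p_values: dict[str, float]  # Wald
    coefficients: dict[str, float]  # log-odds, includes "intercept"
    trace: list[dict] = field(default_factory=list)
    llf: float = math.nan

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(table), self.coefficients["intercept"], dtype=float)
        for v in self.variables:
            eta += self.coefficients[v] * table[v].to_numpy(dtype=float)
        return 1.0 / (1.0 + np.exp(-eta))


def _safe_exp(x: float) -> float:
    """exp() that saturates to inf/0 instead of overflowing (per-unit odds
    ratios of tiny-scale features can exceed the float range)."""
    try:
        return math.exp(x)
    except OverflowError:
        return math.inf if x > 0 else 0.0


def _fit_logit(y: np.ndarray, X: np.ndarray):
    """Newton-fit logistic; raises SeparationError on (quasi-)separation."""
    model = sm.Logit(y, X)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(disp=0, method="newton", maxiter=100)
    except Exception as exc:  # PerfectSeparationError, LinAlgError, ...
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    if not np.all(np.isfinite(res.params)) or np.any(np.abs(res.params[1:]) > 1e3):
        raise SeparationError("diverging coefficients suggest perfect separation")
    if not res.mle_retvals.get("converged", True):
        # a log-likelihood at (numerically) zero means perfect prediction
        if res.llf > -1e-6 or np.any(np.abs(res.params[1:]) > 30):
            raise SeparationError(
                "perfect separation: likelihood unbounded, coefficients diverge"
            )
        with warnings.catch_warnings():  # ill-conditioned Hessian: retry quasi-Newton
            warnings.simplefilter("ignore")
            res = model.fit(disp=0, method="bfgs", maxiter=500)
        if not res.mle_retvals.get("converged", True) or np.any(np.abs(res.params[1:]) > 30):
            raise SeparationError("logistic fit did not converge (quasi-separation?)")
    return res

def stepwise_logistic(
    table: pd.DataFrame,
    candidates: list[str],
    outcome_col: str = "class_label",
    positive_class: str = "INV",
    removal_p: float = 0.10,
) -> LogisticModel:
    """Backward-stepwise logistic regression for invasive vs AIS/MIA.

    Starts from the full model over ``candidates`` (which callers should
    pre-filter by the ANOVA P < 0.10 screen and the VIF screen).  At each
    step the variable with the largest likelihood-ratio removal-test P is
    dropped if that P exceeds ``removal_p``; elimination stops when every
    remaining variable's removal P is <= ``removal_p``.  Retained variables
    are reported with odds ratio, Wald 95% CI and Wald P, plus the full
    selection trace.  Perfect separation raises ``SeparationError`` instead
    of silently diverging.
    """
    y = (table[outcome_col] == positive_class).to_numpy(dtype=float)
    if y.min() == y.max():
        raise DegenerateSampleError("single-class outcome: logistic model undefined")
    for c in candidates:
        if c not in table.columns:
            raise MissingFeatureError(f"candidate {c!r} not in table")
    sub = table[candidates].astype(float)
    ok = np.isfinite(sub.to_numpy()).all(axis=1) if candidates else np.ones(len(y), bool)
    sub, y = sub.loc[ok], y[np.asarray(ok)]

    # predictors are standardised for the Newton fit only; coefficients are
    # reported back on the raw scale (LR and Wald tests are unaffected)
    mu = {v: float(sub[v].mean()) for v in candidates}
    sd = {v: float(sub[v].std(ddof=0)) or 1.0 for v in candidates}

    current = list(candidates)
    trace: list[dict] = []

    def fit(vars_: list[str]):
        cols = [(sub[v].to_numpy() - mu[v]) / sd[v] for v in vars_]
        X = np.column_stack([np.ones(len(y))] + cols)
        return _fit_logit(y, X)

    res = fit(current)
    while current:
        removal = {}
        for v in current:
            reduced = [w for w in current if w != v]
            res_red = fit(reduced)
            lr = 2.0 * (res.llf - res_red.llf)
            removal[v] = float(sps.chi2.sf(max(lr, 0.0), df=1))
        worst = max(removal, key=lambda nm: removal[nm])
        trace.append({"variables": list(current), "removal_p": dict(removal),
                      "removed": worst if removal[worst] > removal_p else None})
        if removal[worst] > removal_p:
            current.remove(worst)
            res = fit(current)
        else:
            break

    intercept = float(res.params[0])
    coef: dict[str, float] = {}
    ors: dict[str, float] = {}
    cis: dict[str, tuple[float, float]] = {}
    pvs: dict[str, float] = {}
    z = sps.norm.ppf(0.975)
    for i, v in enumerate(current, start=1):
        beta = float(res.params[i]) / sd[v]  # back to the raw scale
        se = float(res.bse[i]) / sd[v]
        intercept -= beta * mu[v]
        coef[v] = beta
        ors[v] = _safe_exp(beta)
        cis[v] = (_safe_exp(beta - z * se), _safe_exp(beta + z * se))
        pvs[v] = float(res.pvalues[i])
    coef["intercept"] = intercept
    return LogisticModel(
        variables=current, odds_ratios=ors, ci_95=cis, p_values=pvs,
        coefficients=coef, trace=trace, llf=float(res.llf),
    )


# ---------------------------------------------------------------------------
# ROC analysis


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_95: tuple[float, float]
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def roc_auc(
    scores: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
) -> RocResult:
    """AUC with tie-aware trapezoidal integration and bootstrap 95% CI.

    The AUC equals the Mann-Whitney concordance probability (ties get half
    credit).  The CI is a stratified bootstrap (resampling positives and
    negatives separately) with ``n_boot`` resamples and a fixed seed.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise DegenerateSampleError("single-class labels: ROC undefined")
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, thr = roc_curve(labels, scores)
    rng = np.random.default_rng(seed)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    boots = np.empty(n_boot)
    for b in range(n_boot):
        ps = rng.choice(pos, size=pos.size, replace=True)
        ns = rng.choice(neg, size=neg.size, replace=True)
        bs = np.concatenate([ps, ns])
        bl = np.concatenate([np.ones(ps.size), np.zeros(ns.size)])
        boots[b] = roc_auc_score(bl, bs)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return RocResult(auc=auc, ci_95=(float(lo), float(hi)), fpr=fpr, tpr=tpr, thresholds=thr)


# ---------------------------------------------------------------------------
# the two-threshold invasiveness rule


@dataclass(frozen=True)
class ThresholdRule:
    """Predict invasive adenocarcinoma when BOTH thresholds are met.

    Defaults are the published operating point: 75th-percentile attenuation
    >= -470 HU and entropy >= 7.90 bits, inclusive at the boundary.
    """

    p75_cutoff_hu: float = -470.0
    entropy_cutoff_bits: float = 7.90


def apply_rule(features: pd.Series | dict, rule: ThresholdRule = ThresholdRule()) -> bool:
    """True (predicted invasive) iff p75 and entropy both meet their cutoffs."""
    try:
        p75 = features["p75_hu"]
        ent = features["entropy_bits"]
    except KeyError as exc:
        raise MissingFeatureError(f"rule needs p75_hu and entropy_bits: {exc}") from exc
    if p75 is None or ent is None or not (np.isfinite(p75) and np.isfinite(ent)):
        raise MissingFeatureError("rule features missing or non-finite")
    return bool(p75 >= rule.p75_cutoff_hu and ent >= rule.entropy_cutoff_bits)


def evaluate_rule(
    table: pd.DataFrame,
    rule: ThresholdRule = ThresholdRule(),
    outcome_col: str = "class_label",
    positive_class: str = "INV",
) -> dict:
    """Cohort-level confusion statistics of the two-threshold rule.

    Returns rule-positive count, true positives among rule-positives, PPV,
    sensitivity, specificity and the AUC of the binary rule itself.
    """
    pred = np.array([apply_rule(row, rule) for _, row in table.iterrows()])
    truth = (table[outcome_col] == positive_class).to_numpy()
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))
    n_pos = tp + fp
    out = {
        "n_rule_positive": n_pos,
        "true_positive": tp,
        "false_positive": fp,
        "false_negative": fn,
        "true_negative": tn,
        "ppv": tp / n_pos if n_pos else math.nan,
        "sensitivity": tp / (tp + fn) if (tp + fn) else math.nan,
        "specificity": tn / (tn + fp) if (tn + fp) else math.nan,
    }
    if truth.min() != truth.max():
        out["auc_binary_rule"] = float(roc_auc_score(truth.astype(int), pred.astype(float)))
    else:
        out["auc_binary_rule"] = math.nan
    return out
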