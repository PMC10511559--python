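"""Cohort-level statistical battery.

Covers the analysis chain used in cross-sectional iron-overload studies:
nonparametric group comparisons (Mann-Whitney, Kruskal-Wallis with
Bonferroni post hoc, Wilcoxon signed-rank, Friedman), Spearman
correlation, chi-square tables, ROC analysis with the Youden-optimal
cutoff (maximum sensitivity + specificity), the DeLong test for two
correlated AUCs, predictive values, a log-normal normative upper limit
(mean + 2 SD on the log scale), and univariate + forward-stepwise
multivariate linear regression with VIF/tolerance collinearity screening.

Standard tests are delegated to scipy.stats / statsmodels; the ROC
machinery, DeLong covariance test and the stepwise/collinearity
composition are implemented here because no installed package exposes
them with the exact conventions required (midpoint cutoffs, specificity
tie-break, placement-value covariance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "NormativeLimit",
    "RocResult",
    "RegressionResult",
    "VariableResult",
    "ConfusionSummary",
    "TestReport",
    "derive_normative_limit",
    "roc_with_youden",
    "delong_compare",
    "delong_auc_variance",
    "predictive_values",
    "compare_groups",
    "compare_paired",
    "friedman_repeated",
    "spearman",
    "chi_square",
    "stepwise_multivariate",
]


# --------------------------------------------------------------------------
# normative limit
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NormativeLimit:
    """Upper normal limit derived as mean + 2 SD on the log scale."""

    n: int
    log_mean: float
    log_sd: float
    upper_limit: float
    epsilon: float


def derive_normative_limit(healthy_values, epsilon: float = 0.1) -> NormativeLimit:
    """Upper limit of normal from healthy measurements (e.g. FF in percent).

    The limit is ``exp(mean(log(x + eps)) + 2*sd(log(x + eps))) - eps``
    with the sample SD (n-1 denominator).  ``epsilon`` (same units as the
    data, default 0.1 percentage points) guards exact zeros, which occur
    in healthy regional fat fractions.
    """
    x = np.asarray(healthy_values, dtype=float)
    if x.size < 3:
        raise ValueError("normative limit requires at least 3 values")
    if np.any(x < 0):
        raise ValueError("values must be non-negative")
    logx = np.log(x + epsilon)
    mu = float(logx.mean())
    sd = float(logx.std(ddof=1))
    return NormativeLimit(
        n=int(x.size),
        log_mean=mu,
        log_sd=sd,
        upper_limit=float(np.exp(mu + 2.0 * sd) - epsilon),
        epsilon=float(epsilon),
    )


# --------------------------------------------------------------------------
# ROC / Youden / DeLong / predictive values
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RocResult:
    auc: float
    auc_ci: tuple[float, float]
    cutoff: float
    sensitivity: float
    specificity: float
    direction: str  # "greater": positive if score > cutoff; "less": score < cutoff
    tp: int
    fp: int
    fn: int
    tn: int
    n: int
    p_value: float


def _validate_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(bool)
    if labels.all() or (~labels).all():
        raise ValueError("both classes must be present")
    return labels


def _auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """Tie-corrected AUC = U / (n1*n0) via midranks; equals the pairwise
    statistic with ties counted 1/2 exactly."""
    ranks = stats.rankdata(scores)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _hanley_mcneil_se(auc: float, n1: int, n0: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)) / (n1 * n0)
    return math.sqrt(max(var, 0.0))


def roc_with_youden(scores, labels, direction: str = "greater") -> RocResult:
    """ROC analysis with the Youden-optimal cutoff.

    The AUC is the tie-corrected Mann-Whitney statistic.  The cutoff is
    chosen by exhaustive scan over midpoints between adjacent sorted
    unique scores (plus one candidate beyond each extreme), maximizing
    sensitivity + specificity; ties are resolved toward higher
    specificity (screening context), then toward the more extreme cutoff.
    ``direction="greater"`` calls a subject positive when the score is
    strictly above the cutoff; ``"less"`` when strictly below.  The 95%
    CI uses the Hanley-McNeil asymptotic SE, and the p-value is a Wald
    test of AUC = 0.5 on the same SE.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _validate_binary(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")

    work = scores if direction == "greater" else -scores
    auc = _auc_mann_whitney(work, labels)

    pos = work[labels]
    neg = work[~labels]
    uniq = np.unique(work)
    candidates = np.concatenate(
        ([uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0])
    )
    sens = (pos[None, :] > candidates[:, None]).mean(axis=1)
    spec = (neg[None, :] <= candidates[:, None]).mean(axis=1)
    youden = sens + spec
    best = youden.max()
    tied = np.flatnonzero(youden >= best - 1e-12)
    # prefer higher specificity among ties, then the larger (more extreme) cutoff
    order = np.lexsort((candidates[tied], spec[tied]))
    pick = tied[order[-1]]

    cut_work = float(candidates[pick])
    tp = int((pos > cut_work).sum())
    fn = len(pos) - tp
    tn = int((neg <= cut_work).sum())
    fp = len(neg) - tn

    n1, n0 = len(pos), len(neg)
    se = _hanley_mcneil_se(auc, n1, n0)
    if se > 0:
        z = (auc - 0.5) / se
        p = 2.0 * stats.norm.sf(abs(z))
        ci = (max(0.0, auc - 1.959963984540054 * se), min(1.0, auc + 1.959963984540054 * se))
    else:
        p = 0.0 if auc != 0.5 else 1.0
        ci = (auc, auc)

    return RocResult(
        auc=auc,
        auc_ci=ci,
        cutoff=cut_work if direction == "greater" else -cut_work,
        sensitivity=float(sens[pick]),
        specificity=float(spec[pick]),
        direction=direction,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        n=int(scores.size),
        p_value=float(p),
    )


def _placement_values(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and DeLong placement values (v10 for positives, v01 for negatives)."""
    pos = scores[labels]
    neg = scores[~labels]
    m, n = pos.size, neg.size
    # midrank formulation (Sun & Xu); O((m+n) log (m+n))
    tz = stats.rankdata(np.concatenate([pos, neg]))
    tx = stats.rankdata(pos)
    ty = stats.rankdata(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return float(auc), v10, v01


def delong_auc_variance(scores, labels) -> tuple[float, float]:
    """AUC and its DeLong variance estimate for a single marker."""
    labels = _validate_binary(labels)
    auc, v10, v01 = _placement_values(np.asarray(scores, dtype=float), labels)
    var = np.var(v10, ddof=1) / v10.size + np.var(v01, ddof=1) / v01.size
    return auc, float(var)


def delong_compare(scores_a, scores_b, labels) -> tuple[float, float]:
    """DeLong test for two correlated AUCs measured on the same subjects.

    Returns ``(auc_a - auc_b, two-sided p)``.  The variance of the AUC
    difference comes from the covariance of the placement values; a zero
    variance (identical scores) yields p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired scores must have equal length")
    labels = _validate_binary(labels)
    if a.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")

    auc_a, v10_a, v01_a = _placement_values(a, labels)
    auc_b, v10_b, v01_b = _placement_values(b, labels)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    delta = auc_a - auc_b
    if var_diff <= 0:
        return float(delta), 1.0 if delta == 0 else 0.0
    z = delta / math.sqrt(var_diff)
    return float(delta), float(2.0 * stats.norm.sf(abs(z)))


@dataclass(frozen=True)
class ConfusionSummary:
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    undefined: tuple[str, ...] = ()


def predictive_values(test_flags, condition_flags) -> ConfusionSummary:
    """Sensitivity, specificity, PPV and NPV from paired binary flags.

    Ratios with an empty denominator (e.g. PPV with no test-positives)
    are reported as NaN and listed in ``undefined`` rather than raising.
    """
    t = np.asarray(test_flags).astype(bool)
    c = np.asarray(condition_flags).astype(bool)
    if t.shape != c.shape:
        raise ValueError("test and condition flags must have equal length")
    tp = int(np.sum(t & c))
    fp = int(np.sum(t & ~c))
    fn = int(np.sum(~t & c))
    tn = int(np.sum(~t & ~c))

    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    return ConfusionSummary(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        sensitivity=ratio(tp, tp + fn, "sensitivity"),
        specificity=ratio(tn, tn + fp, "specificity"),
        ppv=ratio(tp, tp + fp, "ppv"),
        npv=ratio(tn, tn + fn, "npv"),
        undefined=tuple(undefined),
    )


# --------------------------------------------------------------------------
# nonparametric suite
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TestReport:
    test: str
    statistic: float
    p_value: float
    n: int
    details: dict = field(default_factory=dict)
    flags: tuple[str, ...] = ()


def _clean(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    return arr[np.isfinite(arr)]


def compare_groups(groups: dict, alpha: float = 0.05) -> TestReport:
    """Compare a continuous variable across 2+ independent groups.

    Two groups: Mann-Whitney U.  More: Kruskal-Wallis, followed by
    pairwise Mann-Whitney post hoc tests with Bonferroni-adjusted
    p-values in ``details["posthoc"]``.  Groups with fewer than 2
    observations flag the report instead of silently disappearing.
    """
    cleaned = {k: _clean(v) for k, v in groups.items()}
    flags = tuple(f"insufficient_n:{k}" for k, v in cleaned.items() if v.size < 2)
    usable = {k: v for k, v in cleaned.items() if v.size >= 2}
    n = int(sum(v.size for v in usable.values()))
    if len(usable) < 2:
        return TestReport("group_comparison", float("nan"), float("nan"), n, flags=flags + ("insufficient_groups",))

    keys = list(usable)
    pooled = np.concatenate(list(usable.values()))
    if np.all(pooled == pooled[0]):  # degenerate: every observation identical
        return TestReport(
            "mann_whitney" if len(usable) == 2 else "kruskal_wallis",
            0.0, 1.0, n, details={"posthoc": {}} if len(usable) > 2 else {},
            flags=flags + ("all_identical",),
        )
    if len(usable) == 2:
        try:
            stat, p = stats.mannwhitneyu(usable[keys[0]], usable[keys[1]], alternative="two-sided")
        except ValueError:
            stat, p = float("nan"), 1.0
            flags = flags + ("degenerate",)
        return TestReport("mann_whitney", float(stat), float(p), n, flags=flags)

    try:
        stat, p = stats.kruskal(*usable.values())
    except ValueError:  # all values identical
        return TestReport("kruskal_wallis", 0.0, 1.0, n,
                          details={"posthoc": {}}, flags=flags + ("all_identical",))
    posthoc = {}
    pairs = [(i, j) for i in range(len(keys)) for j in range(i + 1, len(keys))]
    for i, j in pairs:
        try:
            _, pp = stats.mannwhitneyu(usable[keys[i]], usable[keys[j]], alternative="two-sided")
        except ValueError:
            pp = 1.0
        posthoc[f"{keys[i]} vs {keys[j]}"] = min(1.0, float(pp) * len(pairs))  # Bonferroni
    return TestReport("kruskal_wallis", float(stat), float(p), n, details={"posthoc": posthoc}, flags=flags)


def compare_paired(x, y) -> TestReport:
    """Wilcoxon signed-rank test for two paired measurements."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 2:
        return TestReport("wilcoxon", float("nan"), float("nan"), int(x.size), flags=("insufficient_n",))
    if np.all(x == y):
        return TestReport("wilcoxon", 0.0, 1.0, int(x.size), flags=("all_identical",))
    stat, p = stats.wilcoxon(x, y, zero_method="zsplit")
    return TestReport("wilcoxon", float(stat), float(p), int(x.size))


def friedman_repeated(*measurements) -> TestReport:
    """Friedman test for repeated measurements on the same subjects
    (e.g. fat fraction over the three pancreatic regions)."""
    arrays = [np.asarray(m, dtype=float) for m in measurements]
    if len(arrays) < 3:
        raise ValueError("Friedman test requires at least 3 repeated measurements")
    mask = np.all(np.isfinite(np.vstack(arrays)), axis=0)
    arrays = [a[mask] for a in arrays]
    n = int(arrays[0].size)
    if n < 3:
        return TestReport("friedman", float("nan"), float("nan"), n, flags=("insufficient_n",))
    stacked = np.vstack(arrays)
    if np.all(stacked == stacked[0]):  # no within-subject variation at all
        return TestReport("friedman", 0.0, 1.0, n, flags=("all_identical",))
    stat, p = stats.friedmanchisquare(*arrays)
    return TestReport("friedman", float(stat), float(p), n)


def spearman(x, y) -> TestReport:
    """Spearman rank correlation with pairwise NaN removal."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < 3:
        return TestReport("spearman", float("nan"), float("nan"), n, flags=("insufficient_n",))
    rho, p = stats.spearmanr(x[mask], y[mask])
    return TestReport("spearman", float(rho), float(p), n)


def chi_square(table) -> TestReport:
    """Chi-square test of independence on a contingency table."""
    table = np.asarray(table, dtype=float)
    # drop empty categories so sparse cohorts do not abort the test
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0] if table.size else table
    if table.size == 0 or table.sum() == 0 or table.shape[0] < 2 or table.shape[1] < 2:
        return TestReport("chi_square", float("nan"), float("nan"), int(table.sum()), flags=("degenerate",))
    res = stats.chi2_contingency(table)
    return TestReport("chi_square", float(res.statistic), float(res.pvalue), int(table.sum()))


# --------------------------------------------------------------------------
# regression
# --------------------------------------------------------------------------

@dataclass
class VariableResult:
    name: str
    beta_univariate: float
    p_univariate: float
    stage: str  # univariate | retained | dropped-by-screen | dropped-by-stepwise | dropped-by-collinearity
    beta_multivariate: float | None = None
    p_multivariate: float | None = None
    vif: float | None = None
    tolerance: float | None = None


@dataclass
class RegressionResult:
    """Univariate screen + forward-stepwise multivariate fit summary."""

    variables: dict[str, VariableResult]
    entered_order: list[str]
    model_f: float | None
    model_p: float | None
    r_squared: float | None
    n: int

    @property
    def retained(self) -> list[str]:
        return [v.name for v in self.variables.values() if v.stage == "retained"]

    def table(self) -> pd.DataFrame:
        rows = []
        for v in self.variables.values():
            rows.append(
                {
                    "variable": v.name,
                    "beta_univariate": v.beta_univariate,
                    "p_univariate": v.p_univariate,
                    "beta_multivariate": v.beta_multivariate,
                    "p_multivariate": v.p_multivariate,
                    "stage": v.stage,
                    "vif": v.vif,
                    "tolerance": v.tolerance,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        if self.model_f is None:
            return "No variable retained; multivariate model not fitted."
        header = f"F = {self.model_f:.2f}; p {'< 0.0001' if self.model_p < 1e-4 else f'= {self.model_p:.4f}'}"
        return header + "\n" + self.table().to_string(index=False)


def _zscore(s: pd.Series) -> pd.Series:
    sd = s.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        return s * 0.0
    return (s - s.mean()) / sd


def _ols_p(y: pd.Series, X: pd.DataFrame):
    model = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    return model


def _vif_tolerance(X: pd.DataFrame) -> dict[str, tuple[float, float]]:
    out = {}
    for col in X.columns:
        others = X.drop(columns=[col])
        if others.shape[1] == 0:
            out[col] = (1.0, 1.0)
            continue
        r2 = sm.OLS(X[col], sm.add_constant(others, has_constant="add")).fit().rsquared
        r2 = min(max(r2, 0.0), 1.0)
        tol = 1.0 - r2
        vif = np.inf if tol <= 0 else 1.0 / tol
        out[col] = (float(vif), float(tol))
    return out


def stepwise_multivariate(
    data: pd.DataFrame,
    outcome: str,
    candidates: list[str],
    entry_p: float = 0.05,
    removal_p: float = 0.10,
    vif_max: float = 5.0,
    tolerance_min: float = 0.20,
) -> RegressionResult:
    """Univariate screen, forward stepwise selection, collinearity screen.

    Procedure: (1) each candidate is regressed on the outcome alone
    (standardized beta, p); only candidates with univariate p < 0.05
    enter stepwise consideration.  (2) Forward stepwise: at each step the
    best remaining candidate enters if its coefficient p < ``entry_p``;
    after each entry, any in-model variable with p >= ``removal_p`` is
    removed.  (3) Collinearity: variables with VIF > 5 or tolerance <
    0.20 are dropped, later entries first.  Rows with missing values in
    the outcome or any candidate are dropped listwise.  All variables are
    z-scored so the reported betas are standardized.

    With no retained variable a valid result is returned with stage
    annotations and no model fit.  Candidate-order invariance holds when
    univariate p-values are untied; exact ties are broken by candidate
    order.
    """
    cols = [outcome] + list(candidates)
    df = data[cols].apply(pd.to_numeric, errors="coerce").dropna()
    n = len(df)
    if n < 10 * len(candidates):
        import warnings as _w

        _w.warn(
            f"n = {n} is below 10x the candidate count ({len(candidates)}); "
            "estimates may be unstable",
            stacklevel=2,
        )
    z = df.apply(_zscore)
    y = z[outcome]

    variables: dict[str, VariableResult] = {}
    screened: list[str] = []
    for name in candidates:
        fit = _ols_p(y, z[[name]])
        beta = float(fit.params[name])
        p = float(fit.pvalues[name])
        stage = "univariate" if (np.isfinite(p) and p < entry_p) else "dropped-by-screen"
        variables[name] = VariableResult(name, beta, p, stage)
        if stage == "univariate":
            screened.append(name)

    # forward stepwise with backward removal
    in_model: list[str] = []
    changed = True
    guard = 0
    while changed and guard < 100:
        guard += 1
        changed = False
        best_name, best_p = None, entry_p
        for name in screened:
            if name in in_model:
                continue
            fit = _ols_p(y, z[in_model + [name]])
            p = float(fit.pvalues[name])
            if np.isfinite(p) and p < best_p:
                best_name, best_p = name, p
        if best_name is not None:
            in_model.append(best_name)
            changed = True
        if in_model:
            fit = _ols_p(y, z[in_model])
            worst = max(in_model, key=lambda v: (fit.pvalues[v] if np.isfinite(fit.pvalues[v]) else np.inf))
            worst_p = fit.pvalues[worst]
            if not np.isfinite(worst_p) or worst_p >= removal_p:
                in_model.remove(worst)
                variables[worst].stage = "dropped-by-stepwise"
                changed = True

    entered_order = list(in_model)
    for name in screened:
        if name not in in_model and variables[name].stage == "univariate":
            variables[name].stage = "dropped-by-stepwise"

    # collinearity screen: drop the later-entering offender until clean
    while len(in_model) >= 2:
        diag = _vif_tolerance(z[in_model])
        offenders = [v for v in in_model if diag[v][0] > vif_max or diag[v][1] < tolerance_min]
        if not offenders:
            break
        victim = max(offenders, key=lambda v: in_model.index(v))
        in_model.remove(victim)
        variables[victim].stage = "dropped-by-collinearity"

    if not in_model:
        return RegressionResult(variables, entered_order, None, None, None, n)

    final = _ols_p(y, z[in_model])
    diag = _vif_tolerance(z[in_model]) if len(in_model) >= 1 else {}
    for name in in_model:
        v = variables[name]
        v.stage = "retained"
        v.beta_multivariate = float(final.params[name])
        v.p_multivariate = float(final.pvalues[name])
        v.vif, v.tolerance = diag.get(name, (1.0, 1.0))

    return RegressionResult(
        variables=variables,
        entered_order=entered_order,
        model_f=float(final.fvalue),
        model_p=float(final.f_pvalue),
        r_squared=float(final.rsquared),
        n=n,
    )
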