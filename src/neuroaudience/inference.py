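"""Inference layer for the segment table and minute-level series.

Covers zero-order Pearson correlations, the Fisher r-to-z difference test
for two correlation coefficients, first-order partial correlation, forward
stepwise regression with backward removal (standardized betas), median-split
models, pooled-variance t-tests, and one-way ANOVA with Bonferroni-adjusted
pairwise post-hocs on square-root-normalized minute values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .recording import DegenerateSeriesError, NeuroaudienceError

__all__ = [
    "CorrelationResult",
    "PartialCorrelationResult",
    "FisherZResult",
    "StepwiseResult",
    "MedianSplitResult",
    "TTestResult",
    "AnovaResult",
    "pearson",
    "fisher_z_difference",
    "dependent_correlation_difference",
    "partial_correlation",
    "stepwise_regression",
    "median_split_models",
    "two_sample_ttest",
    "oneway_anova_bonferroni",
]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p: float

    @property
    def df(self) -> int:
        return self.n - 2

    @property
    def r2(self) -> float:
        return self.r**2


@dataclass(frozen=True)
class PartialCorrelationResult:
    r_partial: float
    control: str
    n: int
    p: float


@dataclass(frozen=True)
class FisherZResult:
    z: float
    p: float
    tails: str


@dataclass(frozen=True)
class StepwiseResult:
    entered: tuple[str, ...]
    std_betas: dict[str, float]
    beta_pvalues: dict[str, float]
    r2: float
    adj_r2: float
    model_p: float
    p_enter: float
    p_remove: float

    @property
    def empty(self) -> bool:
        return not self.entered


@dataclass(frozen=True)
class MedianSplitResult:
    low: StepwiseResult | None
    high: StepwiseResult | None
    n_low: int
    n_high: int
    insufficient: tuple[str, ...] = ()


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    n1: int
    n2: int


@dataclass(frozen=True)
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float
    group_means: dict[str, float]
    pairwise_p: pd.DataFrame
    group_order: tuple[str, ...]


def _finite_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise NeuroaudienceError("vectors must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def pearson(x, y) -> CorrelationResult:
    """Sample Pearson r with a two-tailed p from the t distribution (n-2 df)."""
    x, y = _finite_pair(x, y)
    n = len(x)
    if n < 3:
        raise NeuroaudienceError("need at least 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateSeriesError("zero variance in a correlation input")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), n=n, p=float(res.pvalue))


def fisher_z_difference(
    r1: float, n1: int, r2: float, n2: int, tails: str = "two"
) -> FisherZResult:
    """Fisher r-to-z test for the difference of two correlation coefficients.

    Independent-samples form: z = (atanh r1 - atanh r2) /
    sqrt(1/(n1-3) + 1/(n2-3)); p from the standard normal.
    """
    if not (abs(r1) < 1 and abs(r2) < 1):
        raise NeuroaudienceError("|r| must be < 1 for the Fisher transform")
    if n1 < 4 or n2 < 4:
        raise NeuroaudienceError("need n >= 4 in both samples")
    if tails not in ("one", "two"):
        raise NeuroaudienceError(f"tails must be 'one' or 'two', got {tails!r}")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = stats.norm.sf(abs(z))
    if tails == "two":
        p *= 2.0
    return FisherZResult(z=float(z), p=float(min(p, 1.0)), tails=tails)


def dependent_correlation_difference(
    r_jk: float, r_jh: float, r_kh: float, n: int, tails: str = "two"
) -> FisherZResult:
    """Difference test for two dependent correlations sharing one variable.

    Compares r(j,k) against r(j,h) when both were computed on the same
    sample of size n, accounting for the correlation r(k,h) between the two
    non-shared variables (the Meng-Rosenthal-Rubin form of Steiger's test).
    Offered as the alternative to the independent-samples
    :func:`fisher_z_difference`, which reproduces the published values.
    """
    for r in (r_jk, r_jh):
        if not abs(r) < 1:
            raise NeuroaudienceError("|r| must be < 1 for the Fisher transform")
    if not abs(r_kh) <= 1:
        raise NeuroaudienceError("|r_kh| must be <= 1")
    if n < 4:
        raise NeuroaudienceError("need n >= 4")
    if tails not in ("one", "two"):
        raise NeuroaudienceError(f"tails must be 'one' or 'two', got {tails!r}")
    rbar = (r_jk**2 + r_jh**2) / 2.0
    f = min((1.0 - r_kh) / (2.0 * (1.0 - rbar)), 1.0)
    h = (1.0 - f * rbar) / (1.0 - rbar)
    z = (np.arctanh(r_jk) - np.arctanh(r_jh)) * np.sqrt(
        (n - 3) / (2.0 * (1.0 - r_kh) * h)
    )
    p = stats.norm.sf(abs(z))
    if tails == "two":
        p *= 2.0
    return FisherZResult(z=float(z), p=float(min(p, 1.0)), tails=tails)


def partial_correlation(x, y, control, control_name: str = "control") -> PartialCorrelationResult:
    """First-order partial correlation r_xy.z with p via t (n-3 df).

    Equals the Pearson correlation of the residuals of x and y after
    regressing each on the control variable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(control, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y) & np.isfinite(z)
    x, y, z = x[keep], y[keep], z[keep]
    n = len(x)
    if n < 4:
        raise NeuroaudienceError("need at least 4 observations")
    r_xy = pearson(x, y).r
    r_xz = pearson(x, z).r
    r_yz = pearson(y, z).r
    denom = np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    if denom == 0:
        raise DegenerateSeriesError("control is collinear with an input")
    rp = (r_xy - r_xz * r_yz) / denom
    df = n - 3
    t = rp * np.sqrt(df / max(1e-300, 1 - rp**2))
    p = 2 * stats.t.sf(abs(t), df)
    return PartialCorrelationResult(r_partial=float(rp), control=control_name, n=n, p=float(p))


def _fit_ols(X: pd.DataFrame, y: np.ndarray, cols: list[str]):
    design = sm.add_constant(X[cols].to_numpy(), has_constant="add")
    return sm.OLS(y, design).fit()


def stepwise_regression(
    X: pd.DataFrame,
    y,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> StepwiseResult:
    """Forward-selection / backward-removal multiple regression.

    At each forward step the candidate with the smallest partial p-value
    enters if it clears ``p_enter``; after each entry, included predictors
    whose p-value exceeds ``p_remove`` are removed (worst first).  The final
    model reports standardized betas, R-squared, adjusted R-squared, and the
    overall-F p-value.  An empty model (no predictor clears entry) is a
    flagged result, not an error.
    """
    y = np.asarray(y, dtype=float)
    if len(X) != len(y):
        raise NeuroaudienceError("X and y must have equal length")
    if len(y) <= X.shape[1] + 2:
        raise NeuroaudienceError("too few observations for stepwise selection")
    included: list[str] = []
    candidates = list(X.columns)
    order: list[str] = []
    while True:
        changed = False
        best_p, best_col = None, None
        for col in candidates:
            if col in included:
                continue
            fit = _fit_ols(X, y, included + [col])
            p = fit.pvalues[-1]
            if best_p is None or p < best_p:
                best_p, best_col = p, col
        if best_col is not None and best_p < p_enter:
            included.append(best_col)
            order.append(best_col)
            changed = True
        # backward removal (skip the predictor that just entered)
        while len(included) > 1:
            fit = _fit_ols(X, y, included)
            pvals = dict(zip(included, fit.pvalues[1:]))
            removable = {c: p for c, p in pvals.items() if c != order[-1]}
            worst = max(removable, key=removable.get) if removable else None
            if worst is not None and removable[worst] > p_remove:
                included.remove(worst)
                changed = True
            else:
                break
        if not changed:
            break

    if not included:
        return StepwiseResult((), {}, {}, 0.0, 0.0, 1.0, p_enter, p_remove)
    fit = _fit_ols(X, y, included)
    sd_y = y.std(ddof=1)
    std_betas = {
        c: float(fit.params[i + 1] * X[c].std(ddof=1) / sd_y) for i, c in enumerate(included)
    }
    beta_p = {c: float(fit.pvalues[i + 1]) for i, c in enumerate(included)}
    return StepwiseResult(
        entered=tuple(order),
        std_betas=std_betas,
        beta_pvalues=beta_p,
        r2=float(fit.rsquared),
        adj_r2=float(fit.rsquared_adj),
        model_p=float(fit.f_pvalue),
        p_enter=p_enter,
        p_remove=p_remove,
    )


def median_split_models(
    table: pd.DataFrame,
    split_var: str,
    y_var: str,
    x_vars: list[str],
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    min_rows: int = 8,
) -> MedianSplitResult:
    """Stepwise models on the halves of a median split (ties to the low half)."""
    v = table[split_var].to_numpy(dtype=float)
    med = np.median(v)
    if np.all(v == v[0]):
        raise DegenerateSeriesError("all split values identical: no median split possible")
    low = table.loc[v <= med]
    high = table.loc[v > med]
    insufficient = []
    results = {}
    for name, half in (("low", low), ("high", high)):
        if len(half) < min_rows:
            insufficient.append(name)
            results[name] = None
        else:
            results[name] = stepwise_regression(
                half[x_vars], half[y_var], p_enter=p_enter, p_remove=p_remove
            )
    return MedianSplitResult(
        low=results["low"],
        high=results["high"],
        n_low=len(low),
        n_high=len(high),
        insufficient=tuple(insufficient),
    )


def two_sample_ttest(a, b) -> TTestResult:
    """Pooled-variance two-sample t-test, df = n1 + n2 - 2."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise NeuroaudienceError("need at least 2 values per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise DegenerateSeriesError("zero pooled variance")
    res = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(
        t=float(res.statistic), df=len(a) + len(b) - 2, p=float(res.pvalue), n1=len(a), n2=len(b)
    )


def oneway_anova_bonferroni(
    groups: dict[str, np.ndarray], transform: str | None = "sqrt"
) -> AnovaResult:
    """One-way ANOVA across groups with Bonferroni-adjusted pairwise t-tests.

    With ``transform="sqrt"`` the raw (count-scale, non-negative) values are
    square-root normalized before testing; EEG-score ANOVAs pass
    ``transform=None`` because the scaled scores are already bounded.
    """
    if len(groups) < 2:
        raise NeuroaudienceError("need at least 2 groups")
    data = {}
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        v = v[np.isfinite(v)]
        if len(v) < 2:
            raise NeuroaudienceError(f"group {name!r} needs at least 2 values")
        if transform == "sqrt":
            if np.any(v < 0):
                raise NeuroaudienceError(
                    f"group {name!r} has negative values under the sqrt transform"
                )
            v = np.sqrt(v)
        elif transform is not None:
            raise NeuroaudienceError(f"unknown transform {transform!r}")
        data[name] = v
    names = list(data)
    f, p = stats.f_oneway(*data.values())
    k = len(names)
    n_total = sum(len(v) for v in data.values())
    n_pairs = k * (k - 1) // 2
    pair_p = pd.DataFrame(np.eye(k) * 0 + np.nan, index=names, columns=names)
    for i in range(k):
        for j in range(i + 1, k):
            res = stats.ttest_ind(data[names[i]], data[names[j]], equal_var=True)
            adj = min(1.0, float(res.pvalue) * n_pairs)
            pair_p.iloc[i, j] = adj
            pair_p.iloc[j, i] = adj
    means = {name: float(v.mean()) for name, v in data.items()}
    order = tuple(sorted(names, key=means.get, reverse=True))
    return AnovaResult(
        f=float(f),
        df_between=k - 1,
        df_within=n_total - k,
        p=float(p),
        group_means=means,
        pairwise_p=pair_p,
        group_order=order,
    )
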