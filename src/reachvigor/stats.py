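"""Within-subject statistical suite.

Implements the inferential layer used for this paradigm: balanced
fully-within-subject repeated-measures ANOVA (any number of crossed
factors) with Greenhouse–Geisser sphericity correction, Helmert
contrasts against the pooled factor×participant error term, paired
t-tests with Cohen's d and noncentral-t confidence intervals, partial
eta-squared with noncentral-F (pivot) confidence intervals,
Cousineau–Morey within-subject descriptive CIs, and Pearson
correlations with a single-pass ±3 SD residual outlier screen.

No multiple-testing correction is applied anywhere: each test is
reported at its own two-sided p-value, mirroring the analysis style
this suite reproduces (significance threshold p < .05).

The ANOVA decomposition assumes a complete, balanced design: every
participant contributes exactly one value per factor-level crossing
(condition means, not raw trials).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sst

__all__ = [
    "IncompleteDesignError",
    "UndefinedStatisticError",
    "rm_anova",
    "gg_epsilon",
    "helmert_contrasts",
    "paired_t",
    "partial_eta_squared",
    "eta_squared_ci",
    "cohens_d_ci",
    "within_subject_ci",
    "robust_pearson",
    "differential_scores",
    "PairedTestResult",
    "ContrastResult",
    "CorrelationResult",
]


class IncompleteDesignError(ValueError):
    """A participant is missing one or more condition cells."""


class UndefinedStatisticError(ValueError):
    """The requested statistic is undefined for the given data."""


# ---------------------------------------------------------------------------
# repeated-measures ANOVA

def _subset_means(arr: np.ndarray, keep_axes: tuple) -> np.ndarray:
    drop = tuple(ax for ax in range(arr.ndim) if ax not in keep_axes)
    return arr.mean(axis=drop, keepdims=True) if drop else arr


def _effect_array(arr: np.ndarray, axes: tuple) -> np.ndarray:
    """Inclusion–exclusion estimate of the effect indexed by ``axes``."""
    e = np.zeros((1,) * arr.ndim)
    for r in range(len(axes) + 1):
        for sub in combinations(axes, r):
            sign = (-1) ** (len(axes) - r)
            e = e + sign * _subset_means(arr, sub)
    return e


def _effect_ss(arr: np.ndarray, axes: tuple) -> float:
    e = _effect_array(arr, axes)
    mult = arr.size / e.size
    return float(np.sum(e**2) * mult)


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k−1)×k orthonormal contrast matrix (normalized Helmert rows)."""
    m = np.zeros((k - 1, k))
    for i in range(k - 1):
        m[i, i] = k - 1 - i
        m[i, i + 1 :] = -1.0
        m[i] /= np.linalg.norm(m[i])
    return m


def _effect_contrast_matrix(levels, axes):
    """Kronecker contrast matrix spanning the effect over flattened cells."""
    mats = []
    for ax, k in enumerate(levels):
        if ax in axes:
            mats.append(_orthonormal_contrasts(k))
        else:
            mats.append(np.ones((1, k)) / k)
    m = mats[0]
    for nxt in mats[1:]:
        m = np.kron(m, nxt)
    return m


def gg_epsilon(cov: np.ndarray, k: int | None = None) -> float:
    """Greenhouse–Geisser ε from the covariance of k condition scores.

    Uses the double-centred covariance: ε = tr(S̃)² / ((k−1)·ΣS̃²),
    clamped to [1/(k−1), 1].  ε = 1 under compound symmetry; the lower
    bound is reached for maximally non-spherical covariance.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("cov must be a square matrix")
    if k is None:
        k = cov.shape[0]
    if k < 3:
        raise ValueError("sphericity correction needs at least 3 levels")
    row = cov.mean(axis=0, keepdims=True)
    col = cov.mean(axis=1, keepdims=True)
    s = cov - row - col + cov.mean()
    eps = np.trace(s) ** 2 / ((k - 1) * np.sum(s**2))
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def _epsilon_and_mauchly(Y: np.ndarray, M: np.ndarray, d: int):
    """ε and Mauchly's test from subject×cell scores and a contrast basis."""
    n = Y.shape[0]
    S = np.cov(Y, rowvar=False, ddof=1)
    A = M @ np.atleast_2d(S) @ M.T
    trA = np.trace(A)
    eps = float(np.clip(trA**2 / (d * np.sum(A * A)), 1.0 / d, 1.0))
    W = p = np.nan
    if d >= 2 and n - 1 > d:
        det = np.linalg.det(A)
        if det > 0 and trA > 0:
            W = float(det / (trA / d) ** d)
            f = 1.0 - (2 * d**2 + d + 2) / (6.0 * d * (n - 1))
            chi2 = -(n - 1) * f * np.log(W)
            dof = d * (d + 1) // 2 - 1
            p = float(sst.chi2.sf(chi2, dof))
    return eps, W, p


def _pivot_table(data: pd.DataFrame, dv: str, subject: str, factors):
    levels = [list(pd.unique(data[f])) for f in factors]
    subjects = list(pd.unique(data[subject]))
    shape = (len(subjects),) + tuple(len(l) for l in levels)
    arr = np.full(shape, np.nan)
    sub_idx = {s: i for i, s in enumerate(subjects)}
    lev_idx = [{l: i for i, l in enumerate(ls)} for ls in levels]
    for row in data.itertuples(index=False):
        rd = row._asdict() if hasattr(row, "_asdict") else dict(zip(data.columns, row))
        idx = (sub_idx[rd[subject]],) + tuple(
            lev_idx[j][rd[f]] for j, f in enumerate(factors)
        )
        arr[idx] = rd[dv]
    if np.isnan(arr).any():
        bad = np.argwhere(np.isnan(arr))[0]
        cell = tuple(levels[j][bad[j + 1]] for j in range(len(factors)))
        raise IncompleteDesignError(
            f"participant {subjects[bad[0]]!r} is missing cell {cell}"
        )
    return arr, subjects, levels


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    within,
    eta_ci_level: float = 0.90,
    sphericity_alpha: float = 0.05,
) -> pd.DataFrame:
    """Balanced fully-within-subject repeated-measures ANOVA.

    ``data`` is long format: one row per participant × condition cell.
    Every main effect and interaction of the ``within`` factors is
    tested against its own factor×participant error term.  For effects
    with more than one numerator df, Mauchly's sphericity test is run
    and the Greenhouse–Geisser correction applied when it rejects at
    ``sphericity_alpha``; both uncorrected and corrected p-values are
    always reported (the headline ``p`` column follows the applied
    correction).  Partial eta-squared and its noncentral-F CI accompany
    each effect.
    """
    within = list(within)
    arr, subjects, levels = _pivot_table(data, dv, subject, within)
    n = arr.shape[0]
    if n < 2:
        raise IncompleteDesignError("need at least 2 participants")
    level_sizes = tuple(arr.shape[1:])

    rows = []
    factor_axes = tuple(range(1, arr.ndim))
    for r in range(1, len(factor_axes) + 1):
        for axes in combinations(factor_axes, r):
            name = " * ".join(within[a - 1] for a in axes)
            df1 = int(np.prod([arr.shape[a] - 1 for a in axes]))
            df2 = df1 * (n - 1)
            ss_eff = _effect_ss(arr, axes)
            ss_err = _effect_ss(arr, (0,) + axes)
            ms_eff = ss_eff / df1
            ms_err = ss_err / df2
            if ms_err <= 0:
                raise UndefinedStatisticError(f"zero error variance for {name}")
            F = ms_eff / ms_err
            p_unc = float(sst.f.sf(F, df1, df2))

            eps = 1.0
            W = p_spher = np.nan
            gg_applied = False
            if df1 >= 2:
                Y = arr.reshape(n, -1)
                M = _effect_contrast_matrix(level_sizes, tuple(a - 1 for a in axes))
                eps, W, p_spher = _epsilon_and_mauchly(Y, M, df1)
                gg_applied = bool(np.isfinite(p_spher) and p_spher < sphericity_alpha)
            df1_c, df2_c = df1 * eps, df2 * eps
            p_gg = float(sst.f.sf(F, df1_c, df2_c))
            p = p_gg if gg_applied else p_unc

            eta = partial_eta_squared(F, df1, df2)
            lo, hi = eta_squared_ci(F, df1, df2, level=eta_ci_level)
            rows.append(
                {
                    "effect": name,
                    "df1": df1,
                    "df2": df2,
                    "ss_effect": ss_eff,
                    "ss_error": ss_err,
                    "F": F,
                    "p_uncorrected": p_unc,
                    "gg_epsilon": eps,
                    "df1_corr": df1_c,
                    "df2_corr": df2_c,
                    "p_gg": p_gg,
                    "mauchly_W": W,
                    "mauchly_p": p_spher,
                    "gg_applied": gg_applied,
                    "p": p,
                    "partial_eta_sq": eta,
                    "eta_ci_lo": lo,
                    "eta_ci_hi": hi,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# contrasts and paired tests

@dataclass
class ContrastResult:
    label: str
    estimate: float
    t: float
    df: int
    p: float


def helmert_contrasts(
    table: np.ndarray, labels=("low", "middle", "high"), pooled_error: bool = True
):
    """Helmert contrasts over an ordered 3-level within-subject factor.

    ``table`` is participants × 3 condition means, columns ordered.
    Contrast 1 compares level 1 with the mean of levels 2 and 3;
    contrast 2 compares level 2 with level 3.  With ``pooled_error``
    (default) the t uses the pooled factor×participant error mean
    square with df = 2(n−1) — for n = 34 participants this is the
    t(66) of the reported analyses.  Otherwise each contrast is tested
    as a one-sample t on the per-participant contrast scores (df = n−1).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[1] != 3:
        raise ValueError("table must be participants × 3 levels")
    n, k = table.shape
    weights = [
        (np.array([1.0, -0.5, -0.5]), f"{labels[0]} vs {labels[1]}+{labels[2]}"),
        (np.array([0.0, 1.0, -1.0]), f"{labels[1]} vs {labels[2]}"),
    ]
    results = []
    if pooled_error:
        grand = table.mean()
        resid = table - table.mean(0) - table.mean(1, keepdims=True) + grand
        ms_err = np.sum(resid**2) / ((k - 1) * (n - 1))
        dof = (k - 1) * (n - 1)
        for c, label in weights:
            L = float(table.mean(axis=0) @ c)
            se = np.sqrt(ms_err * np.sum(c**2) / n)
            t = L / se
            results.append(
                ContrastResult(label, L, float(t), dof, float(2 * sst.t.sf(abs(t), dof)))
            )
    else:
        for c, label in weights:
            scores = table @ c
            t, p = sst.ttest_1samp(scores, 0.0)
            results.append(
                ContrastResult(label, float(scores.mean()), float(t), n - 1, float(p))
            )
    return results


@dataclass
class PairedTestResult:
    t: float
    df: int
    p: float
    d: float
    d_ci: tuple
    mean_diff: float


def cohens_d_ci(t: float, n: int, level: float = 0.95) -> tuple:
    """CI for a paired Cohen's d by inverting the noncentral-t distribution."""
    df = n - 1
    alpha = 1.0 - level

    def cdf(nc):
        v = sst.nct.cdf(t, df, nc)
        if np.isnan(v):  # tail underflow in scipy's nct: 0 above t, 1 below
            return 0.0 if nc > t else 1.0
        return float(v)

    def solve(target):
        f = lambda nc: cdf(nc) - target
        lo, hi = t - 15.0, t + 15.0
        return optimize.brentq(f, lo, hi, xtol=1e-8)

    nc_hi = solve(alpha / 2.0)
    nc_lo = solve(1.0 - alpha / 2.0)
    return nc_lo / np.sqrt(n), nc_hi / np.sqrt(n)


def paired_t(x, y, ci_level: float = 0.95) -> PairedTestResult:
    """Paired t-test with difference-score Cohen's d (= t/√n) and its CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    diff = x - y
    if np.allclose(diff.std(ddof=1), 0.0):
        raise UndefinedStatisticError("zero variance of difference scores")
    t, p = sst.ttest_rel(x, y)
    d = float(t) / np.sqrt(n)
    ci = cohens_d_ci(float(t), n, level=ci_level)
    return PairedTestResult(float(t), n - 1, float(p), d, ci, float(diff.mean()))


# ---------------------------------------------------------------------------
# effect sizes

def partial_eta_squared(F: float, df1: float, df2: float) -> float:
    """ηp² = F·df1 / (F·df1 + df2)."""
    if F < 0 or df1 <= 0 or df2 <= 0:
        raise ValueError("need F >= 0 and positive dfs")
    return float(F * df1 / (F * df1 + df2))


def eta_squared_ci(F: float, df1: float, df2: float, level: float = 0.90) -> tuple:
    """Pivot CI for ηp²: invert the noncentral-F CDF for the noncentrality.

    The bound λ solving P(F' ≤ F | λ) = α maps to ηp² = λ/(λ + df1 + df2 + 1);
    the lower bound truncates at 0 when F is small.
    """
    if F < 0 or df1 <= 0 or df2 <= 0:
        raise ValueError("need F >= 0 and positive dfs")
    alpha = 1.0 - level
    N = df1 + df2 + 1

    def lam_for(target):
        f = lambda lam: sst.ncf.cdf(F, df1, df2, lam) - target
        if f(0.0) <= 0:  # even λ=0 puts F below the target quantile
            return 0.0
        hi = max(4.0 * (F * df1 + df1 + df2), 10.0)
        while f(hi) > 0:
            hi *= 2.0
            if hi > 1e8:
                raise UndefinedStatisticError("noncentrality inversion diverged")
        return optimize.brentq(f, 0.0, hi, xtol=1e-10)

    lam_lo = lam_for(1.0 - alpha / 2.0)
    lam_hi = lam_for(alpha / 2.0)
    return lam_lo / (lam_lo + N), lam_hi / (lam_hi + N)


# ---------------------------------------------------------------------------
# descriptive within-subject CIs

def within_subject_ci(table: np.ndarray, level: float = 0.95) -> np.ndarray:
    """Cousineau–Morey within-subject CI half-widths per condition cell.

    Each participant's mean is subtracted (grand mean added back), the
    per-cell SD of the normalized scores is inflated by √(M/(M−1)) for
    M cells, and a t-based half-width is returned per cell.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[1] < 2:
        raise ValueError("need a participants × M table with M >= 2")
    n, M = table.shape
    normalized = table - table.mean(axis=1, keepdims=True) + table.mean()
    sd = normalized.std(axis=0, ddof=1) * np.sqrt(M / (M - 1.0))
    tcrit = sst.t.ppf(0.5 + level / 2.0, n - 1)
    return tcrit * sd / np.sqrt(n)


# ---------------------------------------------------------------------------
# correlations

@dataclass
class CorrelationResult:
    r: float
    p: float
    n_used: int
    removed_points: tuple
    sd_threshold: float


def robust_pearson(x, y, sd_threshold: float = 3.0, screen: bool = True) -> CorrelationResult:
    """Pearson correlation with a single-pass residual outlier screen.

    A least-squares line is fit, points whose residuals exceed
    ``sd_threshold`` residual SDs are removed (one pass, no iteration),
    and r is recomputed on the remainder.  ``screen=False`` reduces to
    a plain Pearson correlation on all points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    removed: tuple = ()
    if screen:
        fit = sst.linregress(x, y)
        resid = y - (fit.intercept + fit.slope * x)
        sd = resid.std(ddof=1)
        if sd > 0:
            mask = np.abs(resid) <= sd_threshold * sd
            removed = tuple(int(i) for i in np.nonzero(~mask)[0])
            x, y = x[mask], y[mask]
    if len(x) < 3:
        raise UndefinedStatisticError("too few points remain after screening")
    r, p = sst.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), len(x), removed, sd_threshold)


# ---------------------------------------------------------------------------
# differential (CS+ − CS−) scores

def differential_scores(
    cond_means: pd.DataFrame,
    measures,
    phases=None,
    subject: str = "participant",
) -> pd.DataFrame:
    """Per-participant CS+ − CS− differences for each measure.

    Cell means are first averaged across positions (and across the
    given ``phases``, e.g. the two test phases), separately per CS
    type; the difference of the two CS marginals is then taken.  A
    participant missing one CS marginal propagates NaN.
    """
    df = cond_means
    if phases is not None:
        df = df[df["phase"].isin(list(phases))]
    rows = []
    for pid, g in df.groupby(subject, sort=True):
        row = {subject: pid}
        marg = g.groupby("cs_type")[list(measures)].mean()
        for m in measures:
            plus = marg[m].get("CS+", float("nan"))
            minus = marg[m].get("CS-", float("nan"))
            row[f"{m}_diff"] = plus - minus
        rows.append(row)
    return pd.DataFrame(rows)
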