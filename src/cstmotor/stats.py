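"""Univariate and multivariate group statistics for tract profiles and
cohort tables.

Covers the segment-wise two-sample t-test with Benjamini-Hochberg FDR
control across the 100 segments of one metric/hemisphere family,
Mann-Whitney U with the rank-biserial-free effect size r = |Z| / sqrt(n),
categorical association (Fisher's exact test when any expected count is
below five, otherwise Pearson's chi-squared with Yates continuity
correction for 2x2 tables), the small-sample-corrected standardised mean
difference (Hedges g) and the first canonical correlation between a
feature block and age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


class StatsError(ValueError):
    """Raised for invalid statistical inputs."""


@dataclass
class GroupTestResult:
    name: str
    statistic: float
    p: float
    effect_size: float | None = None
    ci: tuple[float, float] | None = None
    extra: dict | None = None

    def __post_init__(self) -> None:
        if not (np.isnan(self.p) or 0.0 <= self.p <= 1.0):
            raise StatsError("p-value outside [0, 1]")


@dataclass
class SegmentwiseResult:
    """Per-segment t statistics with raw and FDR-adjusted p-values."""

    t: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray
    mask: np.ndarray           # adjusted p < alpha
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "segment": np.arange(self.t.size), "t": self.t,
            "p_raw": self.p_raw, "p_fdr": self.p_adj,
            "significant": self.mask})


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise StatsError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def segmentwise_ttest_fdr(profiles_c0: np.ndarray, profiles_c1: np.ndarray,
                          alpha: float = 0.05) -> SegmentwiseResult:
    """Two-sample pooled-variance t-test per segment, BH-FDR corrected
    across the segment family.

    Missing segment values (NaN) are omitted per segment.  Segments where
    both groups have zero variance get p = 1 when the means agree and
    p = 0 otherwise.
    """
    a = np.atleast_2d(np.asarray(profiles_c0, dtype=float))
    b = np.atleast_2d(np.asarray(profiles_c1, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise StatsError("groups must share the segment axis")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise StatsError("need >= 2 patients per group")
    n_seg = a.shape[1]
    t = np.zeros(n_seg)
    p = np.ones(n_seg)
    for j in range(n_seg):
        x = a[:, j]
        x = x[~np.isnan(x)]
        y = b[:, j]
        y = y[~np.isnan(y)]
        if x.size < 2 or y.size < 2:
            t[j], p[j] = np.nan, 1.0
            continue
        if x.std() == 0.0 and y.std() == 0.0:
            equal = np.isclose(x.mean(), y.mean())
            t[j] = 0.0 if equal else np.inf * np.sign(x.mean() - y.mean())
            p[j] = 1.0 if equal else 0.0
            continue
        res = sps.ttest_ind(x, y, equal_var=True)
        t[j], p[j] = res.statistic, res.pvalue
    adj = bh_fdr(p)
    return SegmentwiseResult(t=t, p_raw=p, p_adj=adj, mask=adj < alpha, alpha=alpha)


def mannwhitney_r(x, y) -> GroupTestResult:
    """Mann-Whitney U with normal-approximation Z (tie-corrected) and the
    effect size r = |Z| / sqrt(n1 + n2)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise StatsError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    n = n1 + n2
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return GroupTestResult("mannwhitney_u", n1 * n2 / 2.0, 1.0, 0.0)
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return GroupTestResult("mannwhitney_u", u1, 1.0, 0.0)
    z = (u1 - mu) / np.sqrt(sigma2)
    p = 2.0 * sps.norm.sf(abs(z))
    r = abs(z) / np.sqrt(n)
    return GroupTestResult("mannwhitney_u", float(u1), float(min(p, 1.0)),
                           float(r), extra={"z": float(z)})


def categorical_association(table) -> GroupTestResult:
    """Fisher's exact test when any expected count < 5 (2x2 only), else
    Pearson chi-squared (Yates-corrected for 2x2 tables)."""
    tab = np.asarray(table)
    if tab.ndim != 2 or np.any(tab < 0) or not np.issubdtype(tab.dtype, np.integer):
        tab = np.asarray(table, dtype=float)
        if np.any(tab < 0) or np.any(tab != np.round(tab)):
            raise StatsError("counts must be non-negative integers")
        tab = tab.astype(int)
    total = tab.sum()
    if total == 0:
        raise StatsError("contingency table is empty")
    expected = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / total
    if np.any(expected < 5):
        if tab.shape != (2, 2):
            raise StatsError("Fisher branch requires a 2x2 table")
        odds, p = sps.fisher_exact(tab)
        return GroupTestResult("fisher_exact", float(odds), float(p))
    correction = tab.shape == (2, 2)
    chi2, p, dof, _ = sps.chi2_contingency(tab, correction=correction)
    return GroupTestResult("chi2", float(chi2), float(p), extra={"dof": int(dof)})


def hedges_g(m1: float, s1: float, n1: int, m2: float, s2: float,
             n2: int) -> GroupTestResult:
    """Hedges g from group summary statistics, with a large-sample 95% CI.

    g = d * (1 - 3 / (4(n1+n2) - 9)) where d = (m1 - m2) / s_pooled;
    SE = sqrt((n1+n2)/(n1 n2) + g^2 / (2(n1+n2))).
    """
    if n1 < 2 or n2 < 2:
        raise StatsError("need n >= 2 per group")
    if s1 < 0 or s2 < 0:
        raise StatsError("SDs must be >= 0")
    sp = np.sqrt(((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2) / (n1 + n2 - 2))
    if sp == 0:
        raise StatsError("pooled SD is zero")
    d = (m1 - m2) / sp
    corr = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    g = d * corr
    se = np.sqrt((n1 + n2) / (n1 * n2) + g ** 2 / (2.0 * (n1 + n2)))
    t = d * np.sqrt(n1 * n2 / (n1 + n2))
    p = 2.0 * sps.t.sf(abs(t), df=n1 + n2 - 2)
    return GroupTestResult("hedges_g", float(g), float(p), float(g),
                           ci=(float(g - 1.96 * se), float(g + 1.96 * se)))


def cca_first_correlation(X, y, ridge: float = 1e-8) -> float:
    """First canonical correlation between a feature block and age.

    With a single right-hand variable this equals the multiple correlation
    of age on X.  X is standardised internally; a rank-deficient covariance
    is ridge-regularised (with a warning).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise StatsError("X rows must match len(y)")
    if n <= p + 1:
        raise StatsError(f"need rows > columns + 1 (got {n} rows, {p} columns)")
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    Xc = Xc / np.where(sd > 0, sd, 1.0)
    yc = y - y.mean()
    if yc.std() == 0:
        raise StatsError("age vector is constant")
    Sxx = Xc.T @ Xc / (n - 1)
    Sxy = Xc.T @ yc / (n - 1)
    Syy = float(yc @ yc / (n - 1))
    if np.linalg.matrix_rank(Sxx) < p:
        import warnings
        warnings.warn("rank-deficient feature block; ridge-regularising",
                      RuntimeWarning, stacklevel=2)
        Sxx = Sxx + ridge * np.eye(p)
    sol = np.linalg.solve(Sxx, Sxy)
    r2 = float(Sxy @ sol / Syy)
    return float(np.sqrt(np.clip(r2, 0.0, 1.0)))


def results_to_frame(results: dict[str, GroupTestResult]) -> pd.DataFrame:
    """Tidy one-row-per-test table for CSV export."""
    rows = []
    for label, r in results.items():
        rows.append({
            "test": label, "statistic_name": r.name,
            "statistic": r.statistic, "p": r.p,
            "effect_size": r.effect_size,
            "ci_low": r.ci[0] if r.ci else None,
            "ci_high": r.ci[1] if r.ci else None})
    return pd.DataFrame(rows)
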