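"""Normality-gated descriptive statistics and correlation.

Protocol: a sample's distribution is tested with Shapiro–Wilk when n < 5000
and with a Kolmogorov–Smirnov test against a normal with sample-estimated
mean/SD otherwise (a Lilliefors-style usage: the reported p-value is the
standard KS p, which is conservative when parameters are estimated).  A
sample of exactly 5000 takes the KS branch.  Normal samples are described as
mean ± SD and correlated with Pearson's r; non-normal samples as
median/IQR with Spearman's rho.  Significance level 0.05 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

ALPHA = 0.05
SHAPIRO_MAX_N = 5000  # n below this uses Shapiro-Wilk, else KS


@dataclass(frozen=True)
class NormalityResult:
    test_name: str  # "shapiro_wilk" | "kolmogorov_smirnov"
    p_value: float
    normal: bool
    degenerate: bool = False


@dataclass(frozen=True)
class CorrelationReport:
    method: str | None  # "pearson" | "spearman" | None when not computable
    rho: float
    p_value: float
    n: int
    computable: bool = True

    @property
    def significant(self) -> bool:
        return self.computable and self.p_value < ALPHA


@dataclass(frozen=True)
class DescriptiveSummary:
    normal: bool
    center: float  # mean if normal else median
    spread: float  # SD if normal else IQR
    n: int


def normality_test(values: np.ndarray) -> NormalityResult:
    """Branch on sample size: Shapiro-Wilk for n < 5000, KS otherwise."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values for a normality test")
    if np.ptp(x) == 0:
        name = "shapiro_wilk" if x.size < SHAPIRO_MAX_N else "kolmogorov_smirnov"
        return NormalityResult(name, 0.0, normal=False, degenerate=True)
    if x.size < SHAPIRO_MAX_N:
        res = sps.shapiro(x)
        return NormalityResult("shapiro_wilk", float(res.pvalue),
                               normal=res.pvalue >= ALPHA)
    res = sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    return NormalityResult("kolmogorov_smirnov", float(res.pvalue),
                           normal=res.pvalue >= ALPHA)


def correlation(x: np.ndarray, y: np.ndarray) -> CorrelationReport:
    """Pearson when both variables test normal, Spearman otherwise.

    Two-sided p-value; H0 is the absence of correlation.  Zero variance in
    either variable yields a not-computable report.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationReport(None, float("nan"), float("nan"), n,
                                 computable=False)
    both_normal = normality_test(x).normal and normality_test(y).normal
    if both_normal:
        rho, p = sps.pearsonr(x, y)
        return CorrelationReport("pearson", float(rho), float(p), n)
    rho, p = sps.spearmanr(x, y)
    return CorrelationReport("spearman", float(rho), float(p), n)


def describe(values: np.ndarray, assume_normal: bool | None = None) -> DescriptiveSummary:
    """Mean ± SD for normal samples, median/IQR otherwise.

    ``assume_normal`` forces a branch (used for tiny samples); when None the
    branch is chosen by :func:`normality_test` for n >= 3 and defaults to the
    robust (median/IQR) path below that.  The IQR uses linearly interpolated
    quartiles (numpy's default percentile rule).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 1:
        raise ValueError("need at least one value")
    if assume_normal is None:
        assume_normal = x.size >= 3 and normality_test(x).normal
    if assume_normal:
        sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
        return DescriptiveSummary(True, float(x.mean()), sd, x.size)
    q1, q3 = np.percentile(x, [25, 75])
    return DescriptiveSummary(False, float(np.median(x)), float(q3 - q1), x.size)
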