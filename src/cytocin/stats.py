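"""Group-comparison statistics: exact tests, gated two-sample tests,
omnibus tests and the Pearson correlation matrix.

The two-sample path mirrors common biostatistics practice for small cohort
studies: Shapiro-Wilk decides normality for each sample at alpha = 0.05; if
both pass, a Student t-test is used (Bartlett's test choosing the pooled or
Welch form); otherwise a rank test (Mann-Whitney U unpaired, Wilcoxon
signed-rank paired). Every decision is recorded in ``gate_trace`` so a report
can state exactly which test produced each p-value. All tests are two-sided;
no multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TwoByTwo",
    "TestResult",
    "CorrelationResult",
    "fisher_exact",
    "compare_groups",
    "kruskal_wallis",
    "correlation_matrix",
    "ALPHA",
]

ALPHA = 0.05


@dataclass(frozen=True)
class TwoByTwo:
    """A 2x2 contingency table (e.g. carriers/non-carriers x exposed/unexposed)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("2x2 cells must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_two_sided: float
    gate_trace: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_two_sided <= 1.0 or np.isnan(self.p_two_sided)):
            raise ValueError(f"p out of range: {self.p_two_sided}")


def fisher_exact(t: TwoByTwo) -> TestResult:
    """Two-sided Fisher exact test: sum of hypergeometric probabilities of
    tables (with the observed margins) no more probable than the observed one.
    """
    tab = t.as_array()
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("fisher_exact requires all margins > 0")
    odds, p = sps.fisher_exact(tab, alternative="two-sided")
    return TestResult(test_name="fisher_exact", statistic=float(odds), p_two_sided=float(p))


def _is_constant(x: np.ndarray) -> bool:
    return bool(np.ptp(x) == 0)


def _shapiro_normal(x: np.ndarray, label: str, trace: list[str]) -> bool:
    if _is_constant(x):
        trace.append(f"shapiro_{label}: constant sample, treated as non-normal")
        return False
    stat, p = sps.shapiro(x)
    normal = p > ALPHA
    trace.append(f"shapiro_{label} p={p:.4g} {'normal' if normal else 'non-normal'}")
    return normal


def compare_groups(
    x: Sequence[float], y: Sequence[float], paired: bool = False
) -> TestResult:
    """Normality-gated two-sample comparison (see module docstring)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("compare_groups requires at least 3 values per sample")
    if paired and len(x) != len(y):
        raise ValueError("paired comparison requires equal lengths")

    trace: list[str] = []
    if paired and _is_constant(x - y):
        # a deterministic difference: no within-pair variation to test against
        p = 1.0 if (x - y)[0] == 0 else 0.0
        trace.append(f"paired differences constant ({(x - y)[0]:g}), p={p:g}")
        return TestResult("paired_constant_difference", float((x - y)[0]), p,
                          "; ".join(trace))
    normal = _shapiro_normal(x, "x", trace) & _shapiro_normal(y, "y", trace)

    if normal:
        if paired:
            trace.append("paired t-test")
            stat, p = sps.ttest_rel(x, y)
            name = "t_paired"
        else:
            bstat, bp = sps.bartlett(x, y)
            equal_var = bp > ALPHA
            trace.append(
                f"bartlett p={bp:.4g} {'equal-var pooled t' if equal_var else 'welch t'}"
            )
            stat, p = sps.ttest_ind(x, y, equal_var=equal_var)
            name = "t_student" if equal_var else "t_welch"
        return TestResult(name, float(stat), float(p), "; ".join(trace))

    if paired:
        diffs = x - y
        if _is_constant(diffs) and diffs[0] == 0:
            trace.append("wilcoxon signed-rank: all differences zero, p=1")
            return TestResult("wilcoxon_signed_rank", 0.0, 1.0, "; ".join(trace))
        trace.append("wilcoxon signed-rank")
        stat, p = sps.wilcoxon(x, y)
        return TestResult("wilcoxon_signed_rank", float(stat), float(p), "; ".join(trace))

    if _is_constant(np.concatenate([x, y])):
        trace.append("mann-whitney: all values identical, p=1")
        return TestResult("mann_whitney_u", float(len(x) * len(y) / 2), 1.0, "; ".join(trace))
    trace.append("mann-whitney U")
    stat, p = sps.mannwhitneyu(x, y, alternative="two-sided")
    return TestResult("mann_whitney_u", float(stat), float(p), "; ".join(trace))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis rank-based omnibus test with tie correction."""
    if len(groups) < 2:
        raise ValueError("kruskal_wallis requires at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in arrays):
        raise ValueError("each group needs at least 2 values")
    if _is_constant(np.concatenate(arrays)):
        return TestResult("kruskal_wallis", 0.0, 1.0, "all values identical")
    stat, p = sps.kruskal(*arrays)
    return TestResult("kruskal_wallis", float(stat), float(p))


@dataclass(frozen=True)
class CorrelationResult:
    """Pairwise Pearson matrix with |r| > threshold flags.

    ``undefined`` marks pairs involving a constant column, where Pearson r
    does not exist; those entries are NaN in ``r`` and False in ``flagged``.
    """

    r: pd.DataFrame
    flagged: pd.DataFrame
    undefined: pd.DataFrame
    threshold: float


def correlation_matrix(
    variables: pd.DataFrame, threshold: float = 0.5
) -> CorrelationResult:
    """Pairwise Pearson correlations over complete rows.

    Binary variables (e.g. sex) must already be 0/1 encoded; the point-biserial
    caveat of running Pearson on such a column is the caller's to keep in mind.
    """
    df = variables.dropna()
    if len(df) < 3:
        raise ValueError("correlation_matrix requires at least 3 complete rows")
    constant = df.std(ddof=0) == 0
    r = df.corr(method="pearson")
    # pandas yields NaN for constant columns already; make the mask explicit
    undefined = pd.DataFrame(
        np.logical_or.outer(constant.values, constant.values),
        index=r.index,
        columns=r.columns,
    )
    r = r.mask(undefined)
    flagged = (r.abs() > threshold) & ~undefined
    np.fill_diagonal(flagged.values, False)
    return CorrelationResult(r=r, flagged=flagged, undefined=undefined, threshold=threshold)
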