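"""Reliability and agreement statistics for repeated defect measurements.

Covers the validation design used for overlay-card studies: intraclass
correlation (reliability of repeated ratings), Bland–Altman analysis
(agreement between two measurement methods) and a one-way ANOVA comparing
group means across observers/methods.

The default ICC form is the two-way random-effects, absolute-agreement,
single-measure coefficient ICC(2,1),

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n),

with MSR/MSC/MSE the rows (subjects), columns (raters) and error mean
squares of the two-way layout; a one-way form ICC(1,1) is available.
Reliability grades follow the conventional thresholds: good (> 0.75),
fair (0.4–0.75), poor (< 0.4).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .errors import DomainError, UndefinedICCError

__all__ = [
    "ICCResult",
    "BlandAltmanResult",
    "GroupComparison",
    "icc",
    "grade_icc",
    "bland_altman",
    "compare_groups",
    "bland_altman_plot",
]


@dataclass(frozen=True)
class ICCResult:
    value: float
    grade: Literal["good", "fair", "poor"]
    form: str
    n_subjects: int
    n_raters: int


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias, spread and 95 % limits of agreement between two paired series."""

    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    ci_bias: tuple[float, float]
    n: int


@dataclass(frozen=True)
class GroupComparison:
    statistic: float
    p_value: float
    method: str
    n_groups: int


def grade_icc(value: float) -> Literal["good", "fair", "poor"]:
    """Conventional reliability grade: > 0.75 good, 0.4–0.75 fair, < 0.4 poor."""
    if value > 0.75:
        return "good"
    if value >= 0.4:
        return "fair"
    return "poor"


def _validate_table(table) -> np.ndarray:
    m = np.asarray(table, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise DomainError(
            f"ratings table needs >= 2 subjects and >= 2 raters, got shape {m.shape}"
        )
    if not np.all(np.isfinite(m)):
        raise DomainError("ratings table contains missing or non-finite cells")
    return m


def icc(
    table, form: Literal["twoway_random_single", "oneway"] = "twoway_random_single"
) -> ICCResult:
    """Intraclass correlation of a subjects x raters table.

    ``twoway_random_single`` is ICC(2,1) — two-way random effects, absolute
    agreement, single measures; ``oneway`` is ICC(1,1).  Raises
    :class:`UndefinedICCError` when the table has no variance at all (the
    coefficient is then 0/0).
    """
    m = _validate_table(table)
    n, k = m.shape
    grand = m.mean()
    if np.ptp(m) == 0.0:
        raise UndefinedICCError("ratings table is constant; ICC is undefined")
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_total = ((m - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    if form == "twoway_random_single":
        msc = ss_cols / (k - 1)
        mse = ss_err / ((n - 1) * (k - 1))
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        if denom <= 0:
            raise UndefinedICCError("zero total variance in ICC denominator")
        value = (msr - mse) / denom
    elif form == "oneway":
        msw = (ss_cols + ss_err) / (n * (k - 1))
        denom = msr + (k - 1) * msw
        if denom <= 0:
            raise UndefinedICCError("zero total variance in ICC denominator")
        value = (msr - msw) / denom
    else:
        raise DomainError(f"unknown ICC form {form!r}")
    return ICCResult(float(value), grade_icc(float(value)), form, n, k)


def bland_altman(a: Sequence[float], b: Sequence[float]) -> BlandAltmanResult:
    """Bland–Altman agreement between paired series ``a`` and ``b``.

    Differences d = a - b; bias = mean(d); sd = sample SD (n-1 denominator);
    95 % limits of agreement = bias ± 1.96 sd; the 95 % CI of the bias uses
    the t distribution, bias ± t_{0.975, n-1} sd / sqrt(n).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DomainError(f"series must be 1-D and equal length, got {a.shape} vs {b.shape}")
    n = a.size
    if n < 2:
        raise DomainError(f"need at least 2 pairs, got {n}")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    half_ci = float(stats.t.ppf(0.975, n - 1) * sd / math.sqrt(n))
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        ci_bias=(bias - half_ci, bias + half_ci),
        n=n,
    )


def compare_groups(
    groups: Sequence[Sequence[float]], method: Literal["anova", "kruskal"] = "anova"
) -> GroupComparison:
    """Across-group mean comparison (one-way fixed-effects ANOVA by default)."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(g.size < 2 for g in arrays):
        raise DomainError("need >= 2 groups with >= 2 values each")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0.0:
        raise DomainError("all observations identical; group comparison is degenerate")
    if method == "anova":
        res = stats.f_oneway(*arrays)
        return GroupComparison(float(res.statistic), float(res.pvalue), "anova", len(arrays))
    if method == "kruskal":
        res = stats.kruskal(*arrays)
        return GroupComparison(float(res.statistic), float(res.pvalue), "kruskal", len(arrays))
    raise DomainError(f"unknown method {method!r}")


def bland_altman_plot(a, b, result: BlandAltmanResult, path, title: str = "") -> None:
    """Scatter of differences vs means with bias and limit-of-agreement lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter((a + b) / 2.0, a - b, s=18, alpha=0.8, edgecolor="none")
    ax.axhline(result.bias, color="k", lw=1.2, label=f"bias = {result.bias:.3f}")
    for y, lbl in ((result.loa_lower, "-1.96 SD"), (result.loa_upper, "+1.96 SD")):
        ax.axhline(y, color="k", lw=0.8, ls="--")
        ax.annotate(lbl, xy=(1.0, y), xycoords=("axes fraction", "data"),
                    xytext=(-4, 2), textcoords="offset points", ha="right", fontsize=8)
    ax.set_xlabel("mean of methods (%)")
    ax.set_ylabel("difference (%)")
    if title:
        ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
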