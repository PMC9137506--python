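"""Demographic / behavioural group statistics computable from summary
triples (n, mean, SD).

A cohort description table usually prints only per-group summaries, so
the primary interface here takes those triples directly: two-sample
t-tests in both the pooled-variance (Student) and unequal-variance
(Welch-Satterthwaite) flavours, an F pretest of variance homogeneity to
pick between them, Pearson correlation for raw paired samples, and
Bonferroni adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError

__all__ = [
    "GroupSummary",
    "TTestResult",
    "summarize",
    "t_from_summary",
    "t_from_samples",
    "variant_select",
    "pearson_r",
    "bonferroni_adjust",
    "summary_table_tests",
]

Variant = Literal["pooled", "welch"]


@dataclass(frozen=True)
class GroupSummary:
    """Per-group (n, mean, SD) for one variable."""

    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise ConfigurationError("group size must be >= 2")
        if self.sd < 0:
            raise ConfigurationError("SD must be >= 0")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    variant: Variant

    def __post_init__(self):
        if self.df <= 0:
            raise ConfigurationError("df must be positive")


def summarize(x: Sequence[float]) -> GroupSummary:
    x = np.asarray(x, dtype=float)
    return GroupSummary(n=len(x), mean=float(x.mean()), sd=float(x.std(ddof=1)))


def t_from_summary(g1: GroupSummary, g2: GroupSummary,
                   variant: Variant = "pooled") -> TTestResult:
    """Two-sample t-test from summary statistics.

    pooled: t = (m1-m2)/sqrt(s_p^2 (1/n1 + 1/n2)), df = n1+n2-2;
    welch:  t = (m1-m2)/sqrt(s1^2/n1 + s2^2/n2), Welch-Satterthwaite df.
    """
    if variant not in ("pooled", "welch"):
        raise ConfigurationError(f"unknown variant {variant!r}")
    if g1.sd == 0 and g2.sd == 0:
        df = g1.n + g2.n - 2 if variant == "pooled" else float(g1.n + g2.n - 2)
        if g1.mean == g2.mean:
            return TTestResult(t=0.0, df=df, p=1.0, variant=variant)
        t = np.inf if g1.mean > g2.mean else -np.inf
        return TTestResult(t=float(t), df=df, p=0.0, variant=variant)
    res = stats.ttest_ind_from_stats(
        g1.mean, g1.sd, g1.n, g2.mean, g2.sd, g2.n,
        equal_var=(variant == "pooled"))
    if variant == "pooled":
        df = float(g1.n + g2.n - 2)
    else:
        a = g1.sd ** 2 / g1.n
        b = g2.sd ** 2 / g2.n
        df = (a + b) ** 2 / (a ** 2 / (g1.n - 1) + b ** 2 / (g2.n - 1))
    return TTestResult(t=float(res.statistic), df=float(df),
                       p=float(res.pvalue), variant=variant)


def t_from_samples(x1: Sequence[float], x2: Sequence[float],
                   variant: Variant = "pooled") -> TTestResult:
    """Raw-data wrapper around :func:`t_from_summary`."""
    return t_from_summary(summarize(x1), summarize(x2), variant)


def variant_select(g1: GroupSummary, g2: GroupSummary,
                   alpha: float = 0.05) -> Variant:
    """Two-sided F test of the variance ratio; 'welch' when homogeneity
    is rejected at ``alpha``, 'pooled' otherwise."""
    if g1.sd == 0 and g2.sd == 0:
        return "pooled"
    if g1.sd == 0 or g2.sd == 0:
        return "welch"
    F = (g1.sd / g2.sd) ** 2
    cdf = stats.f.cdf(F, g1.n - 1, g2.n - 1)
    p = 2 * min(cdf, 1 - cdf)
    return "welch" if p < alpha else "pooled"


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with a t-transform p-value
    (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ConfigurationError("need paired 1-D samples of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ConfigurationError("samples must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ConfigurationError("zero variance in one of the samples")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def bonferroni_adjust(p_values: Iterable[float], m: int | None = None) -> np.ndarray:
    """Bonferroni: min(1, m * p) for each p (m defaults to the number of
    tests supplied)."""
    p = np.asarray(list(p_values), dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ConfigurationError("p-values must be in [0, 1]")
    m = len(p) if m is None else m
    return np.minimum(1.0, m * p)


def summary_table_tests(table: pd.DataFrame, alpha: float = 0.05,
                        bonferroni_m: int | None = None) -> pd.DataFrame:
    """Run the variance pretest + t-test for every variable of a long
    summary table with columns (variable, group, n, mean, sd).

    The two groups are taken in order of first appearance.  Returns one
    row per variable: variant, t, df, p, p_bonferroni.
    """
    required = {"variable", "group", "n", "mean", "sd"}
    if not required.issubset(table.columns):
        raise ConfigurationError(f"table needs columns {sorted(required)}")
    rows = []
    for variable, sub in table.groupby("variable", sort=False):
        if sub.shape[0] != 2:
            raise ConfigurationError(
                f"variable {variable!r} needs exactly two group rows")
        g = [GroupSummary(int(r.n), float(r.mean), float(r.sd))
             for r in sub.itertuples()]
        variant = variant_select(g[0], g[1], alpha=alpha)
        res = t_from_summary(g[0], g[1], variant)
        rows.append({"variable": variable, "variant": variant,
                     "t": res.t, "df": res.df, "p": res.p})
    out = pd.DataFrame(rows)
    m = bonferroni_m if bonferroni_m is not None else len(out)
    out["p_bonferroni"] = bonferroni_adjust(out["p"], m)
    return out
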