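"""Shared statistical conventions used across the pipeline.

The experimental design repeats a small set of tests: a paired t-test for
within-nucleus compartment comparisons, Welch's t-test for between-group
comparisons (optionally on square-root- or log-transformed values), and a
one-sample t-test on log fold changes against a null value of 1.  They are
collected here so every module reports them identically, including the
handling of degenerate inputs (zero variance), which is flagged rather than
propagated as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "TTestReport",
    "welch_test",
    "paired_test",
    "one_sample_test",
]


@dataclass(frozen=True)
class TTestReport:
    """Outcome of a two-sided t-test plus the group descriptives.

    ``degenerate`` marks inputs on which the statistic is undefined (all
    paired differences zero, or zero variance in a one-sample test); by
    convention the p-value is then reported as 1.0 and ``statistic`` as 0.0.
    """

    test: str
    statistic: float
    p_value: float
    df: float
    group_means: dict = field(default_factory=dict)
    group_sems: dict = field(default_factory=dict)
    degenerate: bool = False


def _descriptives(name: str, x: np.ndarray) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    sem = float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else float("nan")
    return float(np.mean(x)), sem


def welch_test(a, b, names: tuple[str, str] = ("a", "b")) -> TTestReport:
    """Welch's unequal-variance two-sample t-test, two-sided.

    Means and s.e.m. are reported on the scale of the values passed in; the
    caller applies any variance-stabilizing transform beforehand.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Welch's t-test requires at least 2 observations per group")
    mean_a, sem_a = _descriptives(names[0], a)
    mean_b, sem_b = _descriptives(names[1], b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0.0 and vb == 0.0:
        degenerate = True
        t, p = 0.0, 1.0
        df = float(a.size + b.size - 2)
    else:
        degenerate = False
        res = sps.ttest_ind(a, b, equal_var=False)
        t, p = float(res.statistic), float(res.pvalue)
        # Welch-Satterthwaite degrees of freedom
        na, nb = a.size, b.size
        df = float((va / na + vb / nb) ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)))
    return TTestReport(
        test="welch",
        statistic=t,
        p_value=p,
        df=df,
        group_means={names[0]: mean_a, names[1]: mean_b},
        group_sems={names[0]: sem_a, names[1]: sem_b},
        degenerate=degenerate,
    )


def paired_test(a, b, names: tuple[str, str] = ("a", "b")) -> TTestReport:
    """Paired two-sided t-test on matched observations (e.g. NP vs
    nucleoplasm within the same nucleus).

    If every paired difference is exactly zero the statistic is undefined;
    the report is flagged degenerate with p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired test requires equal-length vectors")
    if a.size < 2:
        raise ValueError("paired t-test requires at least 2 pairs")
    mean_a, sem_a = _descriptives(names[0], a)
    mean_b, sem_b = _descriptives(names[1], b)
    d = a - b
    if np.all(d == 0.0) or np.var(d, ddof=1) == 0.0:
        return TTestReport(
            test="paired",
            statistic=0.0,
            p_value=1.0,
            df=float(a.size - 1),
            group_means={names[0]: mean_a, names[1]: mean_b},
            group_sems={names[0]: sem_a, names[1]: sem_b},
            degenerate=True,
        )
    res = sps.ttest_rel(a, b)
    return TTestReport(
        test="paired",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=float(a.size - 1),
        group_means={names[0]: mean_a, names[1]: mean_b},
        group_sems={names[0]: sem_a, names[1]: sem_b},
        degenerate=False,
    )


def one_sample_test(values, popmean: float = 0.0, name: str = "values") -> TTestReport:
    """Student's one-sample two-sided t-test against ``popmean``."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("one-sample t-test requires at least 2 observations")
    mean, sem = _descriptives(name, x)
    if np.var(x, ddof=1) == 0.0:
        return TTestReport(
            test="one_sample",
            statistic=0.0,
            p_value=1.0,
            df=float(x.size - 1),
            group_means={name: mean},
            group_sems={name: sem},
            degenerate=True,
        )
    res = sps.ttest_1samp(x, popmean)
    return TTestReport(
        test="one_sample",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=float(x.size - 1),
        group_means={name: mean},
        group_sems={name: sem},
        degenerate=False,
    )
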