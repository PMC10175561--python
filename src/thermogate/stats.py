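"""Stability/threshold correlation and group-comparison statistics.

Mutational stability changes (ddG, computed externally and supplied as a
table) are correlated with heat-activation thresholds by Pearson's
correlation coefficient; the two-sided p-value comes from the exact
t-transform with n - 2 degrees of freedom and the 95% confidence interval
from the Fisher z transform. Group contrasts mirror common
electrophysiology practice: Student's two-sided unpaired t-test for two
groups, one-way ANOVA for more, with Dunnett or Tukey-Kramer post-hoc
contrasts delegated to scipy's implementations.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import (InsufficientReplicatesError, UndefinedCorrelationError)

__all__ = ["CorrelationResult", "GroupComparison",
           "correlate_ddg_threshold", "pearson_with_ci", "compare_groups"]


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    ci95: tuple[float, float]
    flags: list[str] = field(default_factory=list)


@dataclass
class GroupComparison:
    groups: list[str]
    means: dict[str, float]
    sems: dict[str, float]
    test: str
    statistic: float
    p: float
    df: Optional[float] = None
    posthoc: Optional[pd.DataFrame] = None


def pearson_with_ci(x, y, conf: float = 0.95) -> CorrelationResult:
    """Pearson r with exact-t p-value and Fisher-z confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    flags = []
    if not ok.all():
        flags.append(f"dropped_nan_rows={int((~ok).sum())}")
        x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise UndefinedCorrelationError(f"need >= 3 pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("constant variable; r undefined")
    r, p = sps.pearsonr(x, y)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    if n > 3:
        half = sps.norm.ppf(0.5 + conf / 2) / np.sqrt(n - 3)
        ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    else:
        ci = (-1.0, 1.0)
    return CorrelationResult(r=float(r), p=float(p), n=n, ci95=ci, flags=flags)


def correlate_ddg_threshold(panel: pd.DataFrame) -> CorrelationResult:
    """Correlate per-mutant ddG with activation threshold.

    Expects columns ``ddG_kcal_mol`` and ``threshold_C`` (one row per
    mutant; replicate thresholds should be averaged per mutant upstream).
    """
    for col in ("ddG_kcal_mol", "threshold_C"):
        if col not in panel.columns:
            raise UndefinedCorrelationError(f"panel missing column {col!r}")
    return pearson_with_ci(panel["ddG_kcal_mol"], panel["threshold_C"])


def compare_groups(values_by_group: dict[str, "np.ndarray | list[float]"],
                   test: str = "auto", *, control: Optional[str] = None,
                   posthoc: Optional[str] = None) -> GroupComparison:
    """Compare group means the way electrophysiology figures do.

    ``test='auto'`` picks Student's two-sided unpaired t-test for 2 groups
    and one-way ANOVA for more; 'student_t', 'welch_t' and 'anova_oneway'
    force a choice. ``posthoc`` may be 'dunnett' (requires ``control``) or
    'tukey'; adjusted p-values are family-wise (scipy implementations).
    """
    groups = list(values_by_group)
    arrays = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if len(groups) < 2:
        raise InsufficientReplicatesError("need at least 2 groups")
    for g, a in arrays.items():
        if len(a) < 2:
            raise InsufficientReplicatesError(
                f"group {g!r} has {len(a)} values; need >= 2 for SEM"
            )
    means = {g: float(a.mean()) for g, a in arrays.items()}
    sems = {g: float(a.std(ddof=1) / np.sqrt(len(a))) for g, a in arrays.items()}

    if test == "auto":
        test = "student_t" if len(groups) == 2 else "anova_oneway"
    if test in ("student_t", "welch_t"):
        if len(groups) != 2:
            raise InsufficientReplicatesError("t-test requires exactly 2 groups")
        a, b = (arrays[g] for g in groups)
        res = sps.ttest_ind(a, b, equal_var=(test == "student_t"))
        stat, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    elif test == "anova_oneway":
        res = sps.f_oneway(*arrays.values())
        stat, p, df = float(res.statistic), float(res.pvalue), None
    else:
        raise ValueError(f"unknown test {test!r}")

    post = None
    if posthoc == "dunnett":
        if control is None or control not in arrays:
            raise ValueError("dunnett post-hoc requires a control group name")
        others = [g for g in groups if g != control]
        dres = sps.dunnett(*(arrays[g] for g in others),
                           control=arrays[control])
        post = pd.DataFrame({
            "group": others,
            "control": control,
            "statistic": np.atleast_1d(dres.statistic).astype(float),
            "p_adjusted": np.atleast_1d(dres.pvalue).astype(float),
        })
    elif posthoc == "tukey":
        tres = sps.tukey_hsd(*arrays.values())
        rows = []
        for i, gi in enumerate(groups):
            for j, gj in enumerate(groups):
                if i < j:
                    rows.append((gi, gj, float(tres.statistic[i, j]),
                                 float(tres.pvalue[i, j])))
        post = pd.DataFrame(rows, columns=["group_a", "group_b",
                                           "statistic", "p_adjusted"])
    elif posthoc is not None:
        raise ValueError(f"unknown posthoc {posthoc!r}")

    return GroupComparison(groups=groups, means=means, sems=sems, test=test,
                           statistic=stat, p=p, df=df, posthoc=post)
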