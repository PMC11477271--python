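"""The study-style statistical workflow for fold-change readouts.

Measurements from independent assays are normalised to the control-group
mean ("fold change"), forcing the control to 1; each treated group is then
tested against 1 with a one-sample t test, while between-group questions
use Student's t (two groups, pooled variance) or one-way ANOVA (more).
Normality is screened per sample with Shapiro–Wilk at alpha = 0.05 — a
failing gate logs a warning rather than switching test families — and
multiple comparisons are handled with Bonferroni using an explicit number
of planned comparisons.

Outliers are never removed silently: :func:`exclude_outliers` implements a
documented median ± 3 MAD rule and must be invoked explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "FoldChangeSet",
    "shapiro_gate",
    "fold_changes",
    "one_sample_t_vs_1",
    "group_compare",
    "bonferroni",
    "exclude_outliers",
    "one_vs_control_analysis",
]


@dataclass(frozen=True)
class TestResult:
    """One hypothesis test; ``p_adj`` equals ``p_raw`` until corrected."""

    statistic: float
    df: float
    p_raw: float
    p_adj: float
    n: int
    method: str


@dataclass
class FoldChangeSet:
    """Raw values and their control-normalised fold changes."""

    conditions: np.ndarray
    raw: np.ndarray
    control: str
    fold: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.conditions = np.asarray(self.conditions, dtype=object)
        self.raw = np.asarray(self.raw, float)
        ctrl = self.raw[self.conditions == self.control]
        if ctrl.size == 0:
            raise ValueError(f"control {self.control!r} absent")
        mean = ctrl.mean()
        if mean == 0:
            raise ValueError("control mean is 0; fold change undefined")
        self.fold = self.raw / mean

    def group(self, condition: str) -> np.ndarray:
        return self.fold[self.conditions == condition]


def fold_changes(conditions, values, control: str) -> FoldChangeSet:
    """Normalise ``values`` by the mean of the control condition."""
    return FoldChangeSet(conditions, values, control)


def shapiro_gate(values, alpha: float = 0.05):
    """Shapiro–Wilk normality screen.

    Returns ``(W, p, passed)`` with ``passed = (p >= alpha)``.  Needs at
    least three distinct-capable observations; a constant sample has an
    undefined W and raises.
    """
    x = np.asarray(values, float)
    if x.size < 3:
        raise ValueError("Shapiro–Wilk needs n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: W undefined")
    w, p = sps.shapiro(x)
    return float(w), float(p), bool(p >= alpha)


def one_sample_t_vs_1(fold_values) -> TestResult:
    """Two-sided one-sample t test of mean fold change against 1."""
    x = np.asarray(fold_values, float)
    if x.size < 2:
        raise ValueError("need n >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance")
    n = x.size
    t = (x.mean() - 1.0) / (sd / np.sqrt(n))
    p = 2 * sps.t.sf(abs(t), n - 1)
    return TestResult(statistic=float(t), df=float(n - 1), p_raw=float(p),
                      p_adj=float(p), n=n, method="one-sample t vs 1")


def group_compare(*groups) -> TestResult:
    """Student's t (two groups, pooled variance) or one-way ANOVA (more)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrs = [np.asarray(g, float) for g in groups]
    if any(a.size < 2 for a in arrs):
        raise ValueError("every group needs n >= 2")
    n = sum(a.size for a in arrs)
    if len(arrs) == 2:
        t, p = sps.ttest_ind(arrs[0], arrs[1], equal_var=True)
        df = arrs[0].size + arrs[1].size - 2
        return TestResult(float(t), float(df), float(p), float(p), n,
                          "Student t (pooled)")
    f, p = sps.f_oneway(*arrs)
    df = len(arrs) - 1
    return TestResult(float(f), float(df), float(p), float(p), n,
                      "one-way ANOVA")


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment ``min(1, m * p)`` for ``m`` planned tests."""
    p = np.asarray(p_values, float)
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("m must be >= 1")
    if m < p.size:
        raise ValueError("m must cover all p-values")
    return np.minimum(1.0, m * p)


def exclude_outliers(values, mad_factor: float = 3.0):
    """Drop points farther than ``mad_factor`` scaled MADs from the median.

    The MAD is scaled by 1.4826 for consistency with a normal sigma.
    Returns ``(kept, dropped_mask)``; exclusion is always explicit.
    """
    x = np.asarray(values, float)
    med = np.median(x)
    mad = 1.4826 * np.median(np.abs(x - med))
    if mad == 0:
        return x.copy(), np.zeros(x.size, bool)
    dropped = np.abs(x - med) > mad_factor * mad
    return x[~dropped], dropped


def one_vs_control_analysis(conditions, values, control: str,
                            m: int | None = None) -> pd.DataFrame:
    """Fold-change workflow: normalise, gate, test each group against 1.

    Per non-control group: Shapiro–Wilk screen on its fold values (warning
    on failure), one-sample t vs 1, Bonferroni over the ``m`` planned
    comparisons (default: the number of non-control groups).  Returns a
    tidy DataFrame, one row per group.
    """
    fc = fold_changes(conditions, values, control)
    groups = [g for g in pd.unique(fc.conditions) if g != control]
    if m is None:
        m = len(groups)
    rows = []
    for g in groups:
        x = fc.group(g)
        normal = None
        if x.size >= 3 and np.ptp(x) > 0:
            _, sp, normal = shapiro_gate(x)
            if not normal:
                warnings.warn(f"group {g!r} fails the normality screen "
                              f"(Shapiro p={sp:.3g}); t test reported anyway")
        res = one_sample_t_vs_1(x)
        rows.append({"group": g, "n": res.n, "mean_fold": float(x.mean()),
                     "t": res.statistic, "df": res.df,
                     "p_raw": res.p_raw,
                     "p_adj": float(bonferroni([res.p_raw], m)[0]),
                     "normality_pass": normal})
    return pd.DataFrame(rows).set_index("group")
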