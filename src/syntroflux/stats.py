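"""Comparison layer: t-tests, Benjamini-Hochberg FDR, correlations, fold changes.

Metabolite and extent comparisons between assemblies use a two-sample
Student's t-test (pooled variance by default; Welch available), with
q-values from the Benjamini-Hochberg step-up procedure.  Fold changes are
reported with a ceiling (default 100) rendered as "> 100" when the
denominator vanishes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TTestResult",
    "ComparisonResult",
    "two_sample_t",
    "bh_adjust",
    "pearson",
    "flux_fold_changes",
    "FOLD_CEILING",
]

FOLD_CEILING = 100.0


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class ComparisonResult:
    quantity: str
    group_a: str
    group_b: str
    fold_change: float  # ratio B/A, always >= 1 with direction giving the sign
    direction: str  # "up" (B > A), "down" (B < A), "none"
    capped: bool  # fold change hit the ceiling (zero denominator)
    p_value: float
    q_value: float = float("nan")

    @property
    def fold_label(self) -> str:
        base = f"> {self.fold_change:g}" if self.capped else f"{self.fold_change:.2f}"
        arrow = {"up": " ▲", "down": " ▼", "none": ""}[self.direction]
        return base + arrow


def two_sample_t(a, b, variant: str = "pooled") -> TTestResult:
    """Two-sided two-sample t-test; 'pooled' (Student) or 'welch'."""
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return TTestResult(0.0, len(a) + len(b) - 2, 1.0)
        # degenerate: distinct means, no within-group variance
        return TTestResult(math.inf if a.mean() > b.mean() else -math.inf,
                           len(a) + len(b) - 2, 0.0)
    res = sps.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return TTestResult(float(res.statistic), float(res.df), float(res.pvalue))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, permutation-invariant)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with two-sided p via the t-transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need matched samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def flux_fold_changes(
    samples_a: dict[str, np.ndarray],
    samples_b: dict[str, np.ndarray],
    label_a: str,
    label_b: str,
    variant: str = "pooled",
    ceiling: float = FOLD_CEILING,
    adjust: bool = True,
) -> list[ComparisonResult]:
    """Per-quantity fold change B/A with t-test on replicate samples.

    ``samples_a``/``samples_b`` map a quantity id (e.g. a reaction id) to
    replicate extent samples.  Fold change is reported as a ratio >= 1 with
    a direction flag; a zero denominator caps the ratio at ``ceiling``.
    q-values are BH-adjusted across the family when ``adjust`` is set.
    """
    out: list[ComparisonResult] = []
    for qid in sorted(set(samples_a) & set(samples_b)):
        a = np.asarray(samples_a[qid], dtype=float)
        b = np.asarray(samples_b[qid], dtype=float)
        mean_a, mean_b = a.mean(), b.mean()
        if mean_a == mean_b:
            fold, direction, capped = 1.0, "none", False
        else:
            direction = "up" if mean_b > mean_a else "down"
            hi, lo = max(mean_a, mean_b), min(mean_a, mean_b)
            if lo <= 0:
                fold, capped = ceiling, True
            else:
                fold = hi / lo
                capped = fold > ceiling
                fold = min(fold, ceiling)
        test = two_sample_t(a, b, variant=variant)
        out.append(
            ComparisonResult(qid, label_a, label_b, fold, direction, capped, test.p)
        )
    if adjust and out:
        qs = bh_adjust([c.p_value for c in out])
        out = [
            ComparisonResult(c.quantity, c.group_a, c.group_b, c.fold_change,
                             c.direction, c.capped, c.p_value, float(q))
            for c, q in zip(out, qs)
        ]
    return out
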