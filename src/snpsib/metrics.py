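"""Classification performance measures for case-control prediction.

The central criterion is the harmonic mean of sensitivity and specificity
(HMSS), which weighs the two group-wise accuracies equally and is invariant
to the case:control ratio — the natural choice when cohorts are imbalanced.
Uncertainty is quantified with a stratified percentile bootstrap over
(truth, prediction) pairs with the classifier frozen, and per-SNP marginal
association is measured with a Pearson chi-square test on the 2 x r
label-by-genotype contingency table with a Bonferroni significance cut-off.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "MetricResult",
    "ChiSquareResult",
    "confusion",
    "hmss",
    "sensitivity",
    "specificity",
    "total_accuracy",
    "group_accuracy",
    "bootstrap_ci",
    "chi_square_test",
    "bonferroni_threshold",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion tallies with cases as the positive class."""

    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass(frozen=True)
class MetricResult:
    """A point statistic with its bootstrap mean and percentile CI."""

    point: float
    boot_mean: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int

    def __format__(self, spec: str) -> str:
        spec = spec or ".3f"
        return (
            f"{self.point:{spec}}({self.boot_mean:{spec}}, "
            f"{self.ci_low:{spec}}-{self.ci_high:{spec}})"
        )


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Tally a binary confusion table (1 = case = positive, 0 = control)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: y_true has {y_true.shape}, y_pred has {y_pred.shape}"
        )
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} must be binary 0/1")
    case = y_true == 1
    return ConfusionCounts(
        tp=int((case & (y_pred == 1)).sum()),
        fn=int((case & (y_pred == 0)).sum()),
        tn=int((~case & (y_pred == 0)).sum()),
        fp=int((~case & (y_pred == 1)).sum()),
    )


def sensitivity(c: ConfusionCounts) -> float:
    if c.tp + c.fn == 0:
        raise ValueError("sensitivity undefined: no true cases")
    return c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    if c.tn + c.fp == 0:
        raise ValueError("specificity undefined: no true controls")
    return c.tn / (c.tn + c.fp)


def hmss(c: ConfusionCounts) -> float:
    """Harmonic mean of sensitivity and specificity, 2*se*sp/(se+sp).

    Both classes must be present in the truth.  When se + sp = 0 the
    harmonic mean is taken as its limit value 0, keeping the criterion
    total over all confusion tables.
    """
    se = sensitivity(c)
    sp = specificity(c)
    if se + sp == 0.0:
        return 0.0
    return 2.0 * se * sp / (se + sp)


def total_accuracy(c: ConfusionCounts) -> float:
    """Overall fraction of correct predictions, (tp+tn)/n."""
    if c.n == 0:
        raise ValueError("empty confusion table")
    return (c.tp + c.tn) / c.n


def group_accuracy(c: ConfusionCounts, group: str) -> float:
    """Accuracy within one true group: 'cases' -> sensitivity, 'controls' -> specificity."""
    if group == "cases":
        return sensitivity(c)
    if group == "controls":
        return specificity(c)
    raise ValueError(f"group must be 'cases' or 'controls', got {group!r}")


def bootstrap_ci(
    y_true,
    y_pred,
    statistic: Callable[[ConfusionCounts], float] = hmss,
    n_boot: int = 200,
    level: float = 0.95,
    seed: int = 0,
) -> MetricResult:
    """Stratified percentile bootstrap of a confusion-table statistic.

    Cases and controls are resampled with replacement separately, preserving
    the class counts, over (y_true, y_pred) pairs with the classifier frozen
    — so sensitivity and specificity are defined on every resample.  The CI
    is the (2.5%, 97.5%) percentile interval (for level=0.95) with linear
    interpolation between order statistics.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    c = confusion(y_true, y_pred)
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise ValueError("both classes must be present in y_true")
    rng = np.random.default_rng(seed)
    case_idx = np.flatnonzero(y_true == 1)
    ctrl_idx = np.flatnonzero(y_true == 0)
    # resampling y_true within strata leaves it unchanged; only the paired
    # predictions vary across resamples
    case_pred = y_pred[case_idx]
    ctrl_pred = y_pred[ctrl_idx]
    n_case, n_ctrl = case_idx.size, ctrl_idx.size
    vals = np.empty(n_boot)
    for b in range(n_boot):
        cp = case_pred[rng.integers(0, n_case, n_case)]
        gp = ctrl_pred[rng.integers(0, n_ctrl, n_ctrl)]
        cb = ConfusionCounts(
            tp=int(cp.sum()),
            fn=int(n_case - cp.sum()),
            tn=int(n_ctrl - gp.sum()),
            fp=int(gp.sum()),
        )
        vals[b] = statistic(cb)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(vals, [100 * alpha, 100 * (1 - alpha)])
    return MetricResult(
        point=float(statistic(c)),
        boot_mean=float(vals.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        seed=seed,
    )


def chi_square_test(genotypes, labels) -> ChiSquareResult:
    """Pearson chi-square on the 2 x r label-by-genotype table.

    The genotypic (2 x 3) test is used, matching the 0/1/2 coding of the
    analysis; genotype categories absent from the data are dropped, so
    r is the number of observed categories and df = r - 1.  A monomorphic
    column (r = 1) carries no association: statistic 0, p = 1.
    """
    g = np.asarray(genotypes)
    y = np.asarray(labels)
    if g.shape != y.shape:
        raise ValueError("genotypes and labels must align")
    if (g < 0).any():
        raise ValueError("genotype column contains missing codes; impute first")
    table = np.stack(
        [np.bincount(g[y == 1], minlength=3), np.bincount(g[y == 0], minlength=3)]
    )
    table = table[:, table.sum(axis=0) > 0]
    r = table.shape[1]
    if r <= 1:
        return ChiSquareResult(statistic=0.0, df=0, p_value=1.0)
    res = stats.chi2_contingency(table, correction=False)
    return ChiSquareResult(
        statistic=float(res.statistic), df=int(res.dof), p_value=float(res.pvalue)
    )


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance cut-off alpha/m for m simultaneous tests."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m
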