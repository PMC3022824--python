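"""Two-stage SNP subset selection driven by cross-validated HMSS.

Stage one is a filter: every SNP is scored by the training (resubstitution)
HMSS of a single-feature Fisher LDA and the top-k (1,000 at full scale)
survive.  Stage two wraps a subset search around a classifier, scoring
candidate subsets by the HMSS of pooled out-of-fold predictions from a
stratified k-fold split of the training cohort:

* forward selection (FS) — greedy nested growth;
* sequential forward floating selection (SFFS) — FS seeded with the best
  exhaustive 2-SNP subset, with conditional backward exclusions that must
  strictly improve the best-known criterion at the reduced size;
* exhaustive search over all 1-SNP and 2-SNP subsets;
* a constrained search maximizing accuracy in one group subject to a
  minimum accuracy in the other.

The held-out test cohort never influences any selection decision: searches
choose on training-cohort cross-validation alone and test metrics are
attached to the chosen subsets afterwards, for reporting.  All tie-breaks
are deterministic and test-blind (higher single-SNP training HMSS, then
smaller chi-square p, then rs-id), so a search is bit-reproducible.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import metrics
from .classify import FisherLDA, SIBClassifier
from .genio import GenotypeMatrix
from .metrics import MetricResult, bootstrap_ci, confusion, hmss

__all__ = [
    "ClassifierSpec",
    "FoldSplit",
    "SubsetRecord",
    "SearchTrace",
    "ConstrainedSearchResult",
    "make_folds",
    "cv_hmss",
    "filter_rank",
    "forward_selection",
    "sffs",
    "exhaustive_search",
    "constrained_search",
    "evaluate_on_test",
]

_SEED_MOD = 2**31 - 10_000


@dataclass(frozen=True)
class ClassifierSpec:
    """A recipe for building a classifier inside a search.

    ``kind`` is 'lda' or 'sib'; ``params`` are forwarded to the estimator.
    ``base_seed`` anchors the per-(fold, subset) seeds so every fit in a
    search is independently reproducible.
    """

    kind: str = "sib"
    params: dict = field(default_factory=dict)
    base_seed: int = 0

    def __post_init__(self):
        if self.kind not in ("lda", "sib"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")

    @property
    def tag(self) -> str:
        return self.kind

    def make(self, seed: int = 0):
        if self.kind == "lda":
            return FisherLDA(**self.params)
        return SIBClassifier(random_state=seed, **self.params)


@dataclass(frozen=True)
class FoldSplit:
    """A stratified k-fold assignment of training samples."""

    fold_index: np.ndarray
    k: int

    def held_out(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index == fold)

    def held_in(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index != fold)


def make_folds(labels, k: int = 5, seed: int = 0) -> FoldSplit:
    """Stratified, seeded, deterministic k-fold split."""
    y = np.asarray(labels)
    n_case = int((y == 1).sum())
    n_ctrl = int((y == 0).sum())
    if min(n_case, n_ctrl) < k:
        raise ValueError(
            f"each class needs >= {k} members (have {n_case} cases, {n_ctrl} controls)"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_index = np.empty(y.shape[0], dtype=np.int32)
    for f, (_, held) in enumerate(skf.split(np.zeros_like(y), y)):
        fold_index[held] = f
    return FoldSplit(fold_index=fold_index, k=k)


def _subset_seed(base_seed: int, subset: Sequence[str], fold: int) -> int:
    h = zlib.crc32(",".join(subset).encode())
    return (int(base_seed) + h + 1_000_003 * (fold + 1)) % _SEED_MOD


class _Evaluator:
    """Caches cross-validated evaluations of SNP subsets on one cohort pair."""

    def __init__(self, spec, G_train, y_train, folds: FoldSplit, rotations=None):
        self.spec = spec
        self.G = G_train
        self.y = np.asarray(y_train)
        self.codes = G_train.codes
        self.col = {s: j for j, s in enumerate(G_train.snp_ids)}
        self.folds = folds
        self.rotations = folds.k if rotations is None else int(rotations)
        self._cache: dict[frozenset, tuple[float, np.ndarray, np.ndarray]] = {}

    def _canonical(self, subset: Sequence[str]) -> list[str]:
        return sorted(subset, key=lambda s: self.col[s])

    def cv(self, subset: Sequence[str]):
        """(cv_hmss, y_true_oof, y_pred_oof) for the pooled out-of-fold predictions."""
        key = frozenset(subset)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        sub = self._canonical(subset)
        idx = [self.col[s] for s in sub]
        X = self.codes[:, idx]
        true_parts, pred_parts = [], []
        for f in range(self.rotations):
            tr = self.folds.held_in(f)
            te = self.folds.held_out(f)
            clf = self.spec.make(_subset_seed(self.spec.base_seed, sub, f))
            clf.fit(X[tr], self.y[tr])
            pred_parts.append(clf.predict(X[te]))
            true_parts.append(self.y[te])
        y_true = np.concatenate(true_parts)
        y_pred = np.concatenate(pred_parts)
        value = hmss(confusion(y_true, y_pred))
        out = (value, y_true, y_pred)
        self._cache[key] = out
        return out


def cv_hmss(classifier_spec: ClassifierSpec, G_train, y_train, subset, folds: FoldSplit):
    """Cross-validated HMSS of one subset: pooled out-of-fold confusion table.

    Returns ``(hmss, (y_true_pooled, y_pred_pooled))``.
    """
    if len(subset) == 0:
        raise ValueError("subset must be non-empty")
    ev = _Evaluator(classifier_spec, G_train, y_train, folds)
    value, y_true, y_pred = ev.cv(list(subset))
    return value, (y_true, y_pred)


def filter_rank(G_train, y_train, top_k: int = 1000) -> pd.DataFrame:
    """Stage-one filter: rank SNPs by single-feature LDA training HMSS.

    Each SNP is scored by fitting Fisher LDA on the full training cohort
    with that single feature and measuring the resubstitution HMSS.  Ties
    break toward the smaller chi-square association p-value, then the
    lexicographically smaller rs-id.  Returns the top ``min(top_k, m)``
    SNPs as a DataFrame with columns snp_id / hmss / chisq_p.
    """
    if G_train.has_missing():
        raise ValueError("filter requires a complete (imputed) matrix")
    y = np.asarray(y_train)
    rows = []
    for j, sid in enumerate(G_train.snp_ids):
        x = G_train.codes[:, j : j + 1].astype(float)
        clf = FisherLDA().fit(x, y)
        score = hmss(confusion(y, clf.predict(x)))
        p = metrics.chi_square_test(G_train.codes[:, j], y).p_value
        rows.append((sid, score, p))
    df = pd.DataFrame(rows, columns=["snp_id", "hmss", "chisq_p"])
    df = df.sort_values(
        ["hmss", "chisq_p", "snp_id"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    return df.head(min(top_k, len(df)))


@dataclass(frozen=True)
class SubsetRecord:
    """One evaluated SNP subset with CV and test performance."""

    snp_ids: tuple[str, ...]
    classifier_tag: str
    search_tag: str
    cv_hmss: MetricResult | None = None
    cv_total_acc: MetricResult | None = None
    cv_case_acc: MetricResult | None = None
    cv_control_acc: MetricResult | None = None
    test_hmss: MetricResult | None = None
    test_total_acc: MetricResult | None = None
    test_case_acc: MetricResult | None = None
    test_control_acc: MetricResult | None = None

    @property
    def size(self) -> int:
        return len(self.snp_ids)

    def to_row(self) -> dict:
        row = {
            "size": self.size,
            "snp_ids": ";".join(self.snp_ids),
            "classifier": self.classifier_tag,
            "search": self.search_tag,
        }
        for name in ("cv_hmss", "cv_total_acc", "cv_case_acc", "cv_control_acc",
                     "test_hmss", "test_total_acc", "test_case_acc", "test_control_acc"):
            mr: MetricResult | None = getattr(self, name)
            if mr is None:
                row[name] = ""
            else:
                row[name] = mr.point
                row[name + "_boot_mean"] = mr.boot_mean
                row[name + "_ci_low"] = mr.ci_low
                row[name + "_ci_high"] = mr.ci_high
        return row


@dataclass
class SearchTrace:
    """Per-size best subsets along one search (the data behind the HMSS-vs-size plots)."""

    classifier_tag: str
    search_tag: str
    records: list[SubsetRecord]

    def __post_init__(self):
        sizes = [r.size for r in self.records]
        if sizes != sorted(set(sizes)):
            raise ValueError("trace sizes must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_row() for r in self.records])

    def best(self, by: str = "test_hmss") -> SubsetRecord:
        return max(self.records, key=lambda r: getattr(r, by).point)


def _boot(y_true, y_pred, stat, n_boot, seed) -> MetricResult:
    return bootstrap_ci(y_true, y_pred, statistic=stat, n_boot=n_boot, seed=seed)


def _full_record(ev: _Evaluator, subset, G_test, y_test, search_tag,
                 n_boot: int, seed: int) -> SubsetRecord:
    """CV metrics from pooled out-of-fold pairs + test metrics from a full-train fit."""
    sub = ev._canonical(subset)
    _, cv_true, cv_pred = ev.cv(sub)
    idx = [ev.col[s] for s in sub]
    clf = ev.spec.make(_subset_seed(ev.spec.base_seed, sub, ev.folds.k))
    clf.fit(ev.codes[:, idx], ev.y)
    te_idx = [G_test.snp_ids.index(s) for s in sub]
    te_pred = clf.predict(G_test.codes[:, te_idx])
    y_test = np.asarray(y_test)
    stats = {
        "hmss": hmss,
        "total_acc": metrics.total_accuracy,
        "case_acc": metrics.sensitivity,
        "control_acc": metrics.specificity,
    }
    fields: dict = {}
    for i, (name, stat) in enumerate(stats.items()):
        fields["cv_" + name] = _boot(cv_true, cv_pred, stat, n_boot, (seed + 2 * i) % _SEED_MOD)
        fields["test_" + name] = _boot(y_test, te_pred, stat, n_boot, (seed + 2 * i + 1) % _SEED_MOD)
    return SubsetRecord(
        snp_ids=tuple(subset), classifier_tag=ev.spec.tag, search_tag=search_tag, **fields
    )


def _tiebreak_order(candidates, G_train, y_train) -> list[str]:
    """Candidates in deterministic tie-break order (training HMSS desc, chi-square p asc, rs-id)."""
    sub = G_train.subset_snps(list(candidates))
    ranked = filter_rank(sub, y_train, top_k=len(candidates))
    return ranked["snp_id"].tolist()


def forward_selection(classifier_spec, candidates, G_train, y_train, G_test, y_test,
                      folds: FoldSplit, max_size: int = 40, n_boot: int = 200,
                      seed: int = 0, rotations: int | None = None) -> SearchTrace:
    """Greedy forward selection by cross-validated HMSS.

    At each step the candidate whose addition maximizes the CV HMSS joins
    the subset (ties resolve by the test-blind candidate order).  The trace
    records, per size, the subset with its CV and test metrics; test data
    are used for reporting only.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidates must be non-empty")
    if max_size > len(candidates):
        raise ValueError("max_size exceeds the candidate count")
    order = _tiebreak_order(candidates, G_train, y_train)
    ev = _Evaluator(classifier_spec, G_train, y_train, folds, rotations=rotations)
    selected: list[str] = []
    records = []
    for step in range(max_size):
        best_snp, best_val = None, -np.inf
        for snp in order:
            if snp in selected:
                continue
            val, _, _ = ev.cv(selected + [snp])
            if val > best_val:  # strict: earlier tie-break order wins
                best_val, best_snp = val, snp
        selected.append(best_snp)
        records.append(
            _full_record(ev, tuple(selected), G_test, y_test, "fs", n_boot,
                         (seed + 97 * step) % _SEED_MOD)
        )
    return SearchTrace(classifier_tag=classifier_spec.tag, search_tag="fs", records=records)


def sffs(classifier_spec, candidates, G_train, y_train, G_test, y_test,
         folds: FoldSplit, max_size: int = 35, n_boot: int = 200,
         seed: int = 0, max_iterations: int = 100_000,
         rotations: int | None = None) -> SearchTrace:
    """Sequential forward floating selection by cross-validated HMSS.

    Starts from the best 2-SNP subset found by evaluating all pairs, then
    alternates inclusion steps with conditional exclusions: after each
    inclusion, the element whose removal maximizes CV HMSS is dropped —
    but only if the reduced subset strictly beats the best known CV HMSS
    at that size — and exclusion repeats until no drop is accepted.  A
    best-per-size table is maintained and reported as the trace.
    """
    candidates = list(candidates)
    if len(candidates) < 2:
        raise ValueError("SFFS needs at least two candidates")
    if max_size < 2:
        raise ValueError("max_size must be >= 2")
    order = _tiebreak_order(candidates, G_train, y_train)
    rank = {s: i for i, s in enumerate(order)}
    ev = _Evaluator(classifier_spec, G_train, y_train, folds, rotations=rotations)

    best_per_size: dict[int, tuple[float, tuple[str, ...]]] = {}

    def consider(subset: tuple[str, ...], val: float):
        k = len(subset)
        if k not in best_per_size or val > best_per_size[k][0]:
            best_per_size[k] = (val, subset)

    # exhaustive 2-SNP initialization, in tie-break order
    best_pair, best_val = None, -np.inf
    for pair in combinations(order, 2):
        val, _, _ = ev.cv(list(pair))
        if val > best_val:
            best_val, best_pair = val, pair
    current = list(best_pair)
    consider(tuple(current), best_val)

    iters = 0
    while len(current) < max_size:
        # inclusion
        best_snp, best_val = None, -np.inf
        for snp in order:
            if snp in current:
                continue
            val, _, _ = ev.cv(current + [snp])
            if val > best_val:
                best_val, best_snp = val, snp
        current.append(best_snp)
        consider(tuple(current), best_val)
        if len(current) >= max_size:
            break
        # conditional exclusions
        while len(current) > 2:
            iters += 1
            if iters > max_iterations:
                raise RuntimeError("SFFS exceeded the iteration cap")
            best_drop, best_drop_val = None, -np.inf
            for snp in sorted(current, key=rank.__getitem__):
                reduced = [s for s in current if s != snp]
                val, _, _ = ev.cv(reduced)
                if val > best_drop_val:
                    best_drop_val, best_drop = val, snp
            k = len(current) - 1
            if k in best_per_size and best_drop_val <= best_per_size[k][0]:
                break  # no strict improvement at the reduced size
            current.remove(best_drop)
            consider(tuple(current), best_drop_val)

    records = [
        _full_record(ev, best_per_size[k][1], G_test, y_test, "sffs", n_boot,
                     (seed + 97 * k) % _SEED_MOD)
        for k in sorted(best_per_size)
    ]
    return SearchTrace(classifier_tag=classifier_spec.tag, search_tag="sffs", records=records)


def exhaustive_search(classifier_spec, candidates, G_train, y_train, G_test, y_test,
                      folds: FoldSplit, sizes: Iterable[int] = (1, 2),
                      n_boot: int = 200, seed: int = 0, n_report: int = 10,
                      allow_large: bool = False,
                      rotations: int | None = None) -> list[SubsetRecord]:
    """Evaluate every subset of the requested sizes by CV HMSS.

    Sizes above 2 are combinatorially explosive and require
    ``allow_large=True``.  Returns the top ``n_report`` subsets (per the
    CV ranking with deterministic tie-breaks), each with full CV and test
    metrics; the ranking itself never sees test data.
    """
    sizes = sorted(set(int(s) for s in sizes))
    if any(s < 1 for s in sizes):
        raise ValueError("sizes must be >= 1")
    if max(sizes) > 2 and not allow_large:
        raise ValueError("sizes above 2 require allow_large=True")
    candidates = list(candidates)
    order = _tiebreak_order(candidates, G_train, y_train)
    ev = _Evaluator(classifier_spec, G_train, y_train, folds, rotations=rotations)
    scored: list[tuple[float, tuple[str, ...]]] = []
    for k in sizes:
        for subset in combinations(order, k):
            val, _, _ = ev.cv(list(subset))
            scored.append((val, subset))
    # stable sort: earlier (tie-break-ordered) subsets win ties
    scored.sort(key=lambda t: -t[0])
    top = scored[: min(n_report, len(scored))]
    return [
        _full_record(ev, subset, G_test, y_test, "exhaustive", n_boot,
                     (seed + 97 * i) % _SEED_MOD)
        for i, (_, subset) in enumerate(top)
    ]


@dataclass
class ConstrainedSearchResult:
    """Top subsets maximizing one group's accuracy under a floor on the other's."""

    records: list[SubsetRecord]
    best: SubsetRecord | None
    constrained_group: str
    status: str = "ok"


def constrained_search(classifier_spec, candidates, G_train, y_train, G_test, y_test,
                       folds: FoldSplit, constrained_group: str = "cases",
                       min_acc: float = 0.4, top_n: int = 20,
                       sizes: Iterable[int] = (1, 2), n_boot: int = 200,
                       seed: int = 0, rotations: int | None = None) -> ConstrainedSearchResult:
    """Maximize CV accuracy in one group subject to a floor in the other.

    All subsets of the given sizes whose CV accuracy in ``constrained_group``
    is at least ``min_acc`` are ranked by CV accuracy in the other group;
    the ``top_n`` get test metrics with bootstrap CIs, and the best of
    those by test accuracy in the unconstrained group is reported.
    """
    if constrained_group not in ("cases", "controls"):
        raise ValueError("constrained_group must be 'cases' or 'controls'")
    other = "controls" if constrained_group == "cases" else "cases"
    candidates = list(candidates)
    order = _tiebreak_order(candidates, G_train, y_train)
    ev = _Evaluator(classifier_spec, G_train, y_train, folds, rotations=rotations)
    sizes = sorted(set(int(s) for s in sizes))
    kept: list[tuple[float, tuple[str, ...]]] = []
    for k in sizes:
        for subset in combinations(order, k):
            _, y_true, y_pred = ev.cv(list(subset))
            c = confusion(y_true, y_pred)
            if metrics.group_accuracy(c, constrained_group) >= min_acc:
                kept.append((metrics.group_accuracy(c, other), subset))
    if not kept:
        warnings.warn("no subset satisfies the group-accuracy constraint")
        return ConstrainedSearchResult([], None, constrained_group, status="empty")
    kept.sort(key=lambda t: -t[0])
    top = kept[: min(top_n, len(kept))]
    records = [
        _full_record(ev, subset, G_test, y_test, f"constrained_{constrained_group}",
                     n_boot, (seed + 97 * i) % _SEED_MOD)
        for i, (_, subset) in enumerate(top)
    ]
    attr = "test_control_acc" if other == "controls" else "test_case_acc"
    best = max(records, key=lambda r: getattr(r, attr).point)
    return ConstrainedSearchResult(records, best, constrained_group)


def evaluate_on_test(classifier_spec, subset, G_train, y_train, G_test, y_test,
                     n_boot: int = 200, seed: int = 0,
                     folds: FoldSplit | None = None) -> SubsetRecord:
    """Fit once on the full training cohort and measure the test cohort.

    All test metrics carry stratified bootstrap CIs; CV metrics are included
    when ``folds`` is given.
    """
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    y_train = np.asarray(y_train)
    if folds is not None:
        ev = _Evaluator(classifier_spec, G_train, y_train, folds)
        return _full_record(ev, tuple(subset), G_test, y_test, "eval", n_boot, seed)
    col = {s: j for j, s in enumerate(G_train.snp_ids)}
    sub = sorted(subset, key=col.__getitem__)
    idx = [col[s] for s in sub]
    clf = classifier_spec.make(_subset_seed(classifier_spec.base_seed, sub, 0))
    clf.fit(G_train.codes[:, idx], y_train)
    te_idx = [G_test.snp_ids.index(s) for s in sub]
    pred = clf.predict(G_test.codes[:, te_idx])
    y_test = np.asarray(y_test)
    stats = {
        "hmss": hmss,
        "total_acc": metrics.total_accuracy,
        "case_acc": metrics.sensitivity,
        "control_acc": metrics.specificity,
    }
    fields = {
        "test_" + name: _boot(y_test, pred, stat, n_boot, (seed + i) % _SEED_MOD)
        for i, (name, stat) in enumerate(stats.items())
    }
    return SubsetRecord(
        snp_ids=tuple(subset), classifier_tag=classifier_spec.tag,
        search_tag="eval", **fields
    )
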