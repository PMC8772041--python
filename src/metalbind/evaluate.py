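"""Evaluation protocol: confusion-matrix metrics, stratified fivefold
cross-validation, repeated balanced undersampling, and chain-level 80/20
independent testing.

Metrics are the field's standard quartet on binding-residue prediction:
sensitivity Sn = TP/(TP+FN), specificity Sp = TN/(TN+FP), accuracy
Acc = (TP+TN)/total (all as percentages) and the Matthews correlation
coefficient, with MCC defined as 0 when any factor of its denominator
vanishes.

Cross-validation stratifies fragment-level folds by label (optionally
grouping by chain so no chain straddles folds); the PWM encoder and the
standardizer are refit inside every training fold, so no information from a
test fold leaks into its features.  The undersampling protocol draws, ten
times, a negative sample the size of the positive set, runs CV on each
balanced set and averages the four metrics arithmetically.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .fragments import Fragment
from .pipeline import FragmentPipeline, default_pipeline_factory

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvaluationResult:
    """Confusion counts plus the four derived metrics."""

    tp: int
    fp: int
    tn: int
    fn: int
    sn: float   # percent
    sp: float   # percent
    acc: float  # percent
    mcc: float

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def metrics(tp: int, fp: int, tn: int, fn: int) -> EvaluationResult:
    """Compute Sn/Sp/Acc (percent) and MCC from confusion counts."""
    for name, v in (("tp", tp), ("fp", fp), ("tn", tn), ("fn", fn)):
        if v < 0 or v != int(v):
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    tp, fp, tn, fn = int(tp), int(fp), int(tn), int(fn)
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("no predictions to evaluate")
    sn = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    sp = 100.0 * tn / (tn + fp) if tn + fp else 0.0
    acc = 100.0 * (tp + tn) / total
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return EvaluationResult(tp=tp, fp=fp, tn=tn, fn=fn, sn=sn, sp=sp, acc=acc, mcc=mcc)


def from_predictions(y_true, y_pred) -> EvaluationResult:
    """Metrics from parallel label/call arrays."""
    y_true = np.asarray(y_true, dtype=bool)
    y_pred = np.asarray(y_pred, dtype=bool)
    if y_true.shape != y_pred.shape:
        raise ValueError("label and prediction arrays differ in shape")
    tp = int(np.sum(y_true & y_pred))
    fp = int(np.sum(~y_true & y_pred))
    tn = int(np.sum(~y_true & ~y_pred))
    fn = int(np.sum(y_true & ~y_pred))
    return metrics(tp, fp, tn, fn)


@dataclass(frozen=True)
class MetricSummary:
    """Averaged Sn/Sp/Acc/MCC (no confusion counts — means of ratios)."""

    sn: float
    sp: float
    acc: float
    mcc: float


def summarize(results: Sequence[EvaluationResult]) -> tuple[MetricSummary, MetricSummary]:
    """(mean, standard deviation) of the four metrics over a result list."""
    arr = np.array([[r.sn, r.sp, r.acc, r.mcc] for r in results])
    mean = arr.mean(axis=0)
    std = arr.std(axis=0)
    return MetricSummary(*mean), MetricSummary(*std)


@dataclass
class CVResult:
    folds: list[EvaluationResult]
    pooled: EvaluationResult  # micro-pooled confusion counts over folds


PipelineFactory = Callable[[int], FragmentPipeline]


def kfold_cv(
    fragments: Sequence[Fragment],
    pipeline_factory: PipelineFactory | None = None,
    k: int = 5,
    seed: int = 0,
    group_by_chain: bool = False,
) -> CVResult:
    """Stratified k-fold cross-validation over fragments.

    Each fold trains a fresh pipeline (PWMs, standardizer and network refit on
    the training fold only) and predicts the held-out fold; every fragment is
    tested exactly once.  ``group_by_chain`` keeps all fragments of a chain in
    one fold.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    fragments = list(fragments)
    factory = pipeline_factory or default_pipeline_factory()
    y = np.array([int(f.label) for f in fragments])
    idx = np.arange(len(fragments))
    if group_by_chain:
        groups = np.array([f.chain_id for f in fragments])
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(idx, y, groups)
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(idx, y)

    fold_results = []
    seeds = np.random.SeedSequence(seed).generate_state(k) % (2**31)
    for fold, (tr, te) in enumerate(splits):
        if len(np.unique(y[tr])) < 2:
            raise ValueError(f"fold {fold}: training part contains a single class")
        pipe = factory(int(seeds[fold]))
        pipe.fit([fragments[i] for i in tr])
        _, calls = pipe.predict([fragments[i] for i in te])
        fold_results.append(from_predictions(y[te].astype(bool), calls))
        logger.info("fold %d/%d: MCC %.3f", fold + 1, k, fold_results[-1].mcc)
    pooled = metrics(
        tp=sum(r.tp for r in fold_results),
        fp=sum(r.fp for r in fold_results),
        tn=sum(r.tn for r in fold_results),
        fn=sum(r.fn for r in fold_results),
    )
    return CVResult(folds=fold_results, pooled=pooled)


@dataclass
class UndersampleResult:
    repeats: list[CVResult]
    mean: MetricSummary
    std: MetricSummary


def undersample_eval(
    positives: Sequence[Fragment],
    negatives: Sequence[Fragment],
    pipeline_factory: PipelineFactory | None = None,
    repeats: int = 10,
    seed: int = 0,
    k: int = 5,
) -> UndersampleResult:
    """Repeated balanced undersampling: each repeat draws |positives| negatives
    without replacement, runs stratified k-fold CV on the balanced set, and the
    repeats' pooled metrics are arithmetically averaged."""
    positives, negatives = list(positives), list(negatives)
    if not positives:
        raise ValueError("no positive fragments")
    if len(negatives) < len(positives):
        raise ValueError(
            f"{len(negatives)} negatives cannot balance {len(positives)} positives"
        )
    rng = np.random.default_rng(seed)
    repeat_seeds = np.random.SeedSequence(seed).generate_state(repeats) % (2**31)
    results = []
    for r in range(repeats):
        picked = rng.choice(len(negatives), size=len(positives), replace=False)
        balanced = positives + [negatives[i] for i in picked]
        results.append(kfold_cv(balanced, pipeline_factory, k=k, seed=int(repeat_seeds[r])))
        logger.info("undersample repeat %d/%d: pooled MCC %.3f",
                    r + 1, repeats, results[-1].pooled.mcc)
    mean, std = summarize([cv.pooled for cv in results])
    return UndersampleResult(repeats=results, mean=mean, std=std)


@dataclass(frozen=True)
class SplitPlan:
    """Chain-level train/test assignment (whole chains, never fragments)."""

    unit: str
    assignments: dict[str, str]  # chain_id -> "train" | "test"
    seed: int

    @property
    def train_ids(self) -> list[str]:
        return [c for c, s in self.assignments.items() if s == "train"]

    @property
    def test_ids(self) -> list[str]:
        return [c for c, s in self.assignments.items() if s == "test"]


def chain_split(chains, train_fraction: float = 0.8, seed: int = 0) -> SplitPlan:
    """Assign whole chains to train (floor(fraction * n)) and test sides."""
    chains = list(chains)
    if len(chains) < 2:
        raise ValueError("need at least 2 chains to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(chains))
    n_train = int(math.floor(train_fraction * len(chains)))
    assignments = {}
    for rank, i in enumerate(order):
        assignments[chains[i].chain_id] = "train" if rank < n_train else "test"
    for side in ("train", "test"):
        ids = {c for c, s in assignments.items() if s == side}
        if not any(ch.n_binding for ch in chains if ch.chain_id in ids):
            logger.warning("%s side of the chain split has zero positive residues", side)
    return SplitPlan(unit="chain", assignments=assignments, seed=seed)


@dataclass
class IndependentResult:
    """Balanced-training CV plus imbalanced independent-test metrics."""

    plan: SplitPlan
    train_cv: UndersampleResult
    test_repeats: list[EvaluationResult]
    test_mean: MetricSummary
    test_std: MetricSummary


def independent_eval(
    chains,
    L: int = 9,
    pipeline_factory: PipelineFactory | None = None,
    train_fraction: float = 0.8,
    repeats: int = 10,
    seed: int = 0,
    k: int = 5,
) -> IndependentResult:
    """Chain-level 80/20 protocol.

    Training chains feed the repeated balanced undersampling CV; for the
    independent test, each repeat fits a pipeline on one balanced training
    draw and predicts every fragment of the withheld chains (imbalanced, as
    deployment would see them); test metrics are averaged over repeats.
    """
    from .fragments import extract_all

    chains = list(chains)
    factory = pipeline_factory or default_pipeline_factory()
    plan = chain_split(chains, train_fraction=train_fraction, seed=seed)
    train_chains = [c for c in chains if plan.assignments[c.chain_id] == "train"]
    test_chains = [c for c in chains if plan.assignments[c.chain_id] == "test"]
    train_frags = extract_all(train_chains, L=L)
    test_frags = extract_all(test_chains, L=L)
    positives = [f for f in train_frags if f.label]
    negatives = [f for f in train_frags if not f.label]

    train_cv = undersample_eval(positives, negatives, factory,
                                repeats=repeats, seed=seed, k=k)

    rng = np.random.default_rng(seed)
    fit_seeds = np.random.SeedSequence((seed, 1)).generate_state(repeats) % (2**31)
    y_test = np.array([f.label for f in test_frags], dtype=bool)
    test_results = []
    for r in range(repeats):
        picked = rng.choice(len(negatives), size=len(positives), replace=False)
        balanced = positives + [negatives[i] for i in picked]
        pipe = factory(int(fit_seeds[r]))
        pipe.fit(balanced)
        _, calls = pipe.predict(test_frags)
        test_results.append(from_predictions(y_test, calls))
    test_mean, test_std = summarize(test_results)
    return IndependentResult(plan=plan, train_cv=train_cv,
                             test_repeats=test_results,
                             test_mean=test_mean, test_std=test_std)
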