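"""Evaluation: precision/recall/F over the TRUE class, document-level k-fold
cross-validation, and training-set-size (learning-curve) experiments.

The F-score is computed over TRUE-labelled relations only, since those are
the potential adverse event relations of interest; FALSE is the background
class.  Cross-validation folds partition *documents*, never instances, so
candidates from one case report cannot leak between train and test.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass, field
from typing import Sequence

from .corpus_model import Corpus, Label
from .instance_builder import RelationCandidate, build_dataset
from .relation_classifier import FeatureCache, predict, train
from .slk_features import KernelParams, feature_map

logger = logging.getLogger(__name__)

DEFAULT_SIZE_LADDER = (10, 20, 50, 100, 200, 500, 1000, 2000)


@dataclass(frozen=True)
class EvalResult:
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f_score: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def prf(tp: int, fp: int, fn: int, tn: int) -> EvalResult:
    """Precision, recall and F over the TRUE class from confusion counts.
    Undefined ratios (zero denominators) are reported as 0."""
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("confusion counts must be non-negative")
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    return EvalResult(tp=tp, fp=fp, fn=fn, tn=tn, precision=p, recall=r, f_score=f_from_pr(p, r))


def f_from_pr(p: float, r: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if not (0 <= p <= 1 and 0 <= r <= 1):
        raise ValueError("precision and recall must lie in [0, 1]")
    return 2 * p * r / (p + r) if p + r else 0.0


def confusion(gold: Sequence[Label], predicted: Sequence[Label]) -> tuple[int, int, int, int]:
    if len(gold) != len(predicted):
        raise ValueError("gold and predicted label sequences differ in length")
    tp = sum(1 for g, q in zip(gold, predicted) if g is Label.TRUE and q is Label.TRUE)
    fp = sum(1 for g, q in zip(gold, predicted) if g is Label.FALSE and q is Label.TRUE)
    fn = sum(1 for g, q in zip(gold, predicted) if g is Label.TRUE and q is Label.FALSE)
    tn = sum(1 for g, q in zip(gold, predicted) if g is Label.FALSE and q is Label.FALSE)
    return tp, fp, fn, tn


def _doc_groups(dataset: Sequence[RelationCandidate]) -> dict[str, list[RelationCandidate]]:
    groups: dict[str, list[RelationCandidate]] = {}
    for cd in dataset:
        groups.setdefault(cd.doc_id, []).append(cd)
    return groups


def build_feature_cache(dataset: Sequence[RelationCandidate],
                        params: KernelParams) -> dict[str, dict[str, float]]:
    """Precompute feature maps keyed by instance_id (featurization dominates
    the cost of repeated CV rounds; the maps are params-specific)."""
    return {cd.instance_id: feature_map(cd, params).entries for cd in dataset}


def _fold_assignment(doc_ids: list[str], k: int, rng: random.Random) -> list[list[str]]:
    ids = sorted(doc_ids)
    rng.shuffle(ids)
    folds: list[list[str]] = [[] for _ in range(k)]
    for i, did in enumerate(ids):
        folds[i % k].append(did)
    return folds


def _cv_on_groups(
    groups: dict[str, list[RelationCandidate]],
    k: int,
    params: KernelParams,
    C: float,
    seed: int,
    feature_cache: FeatureCache | None,
) -> tuple[EvalResult, list[EvalResult]]:
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(groups):
        raise ValueError(f"k={k} exceeds number of documents ({len(groups)})")
    folds = _fold_assignment(list(groups), k, random.Random(seed))
    per_fold: list[EvalResult] = []
    totals = [0, 0, 0, 0]
    for fold_ids in folds:
        held = set(fold_ids)
        train_set = [cd for did, cds in groups.items() if did not in held for cd in cds]
        test_set = [cd for did in fold_ids for cd in groups[did]]
        if not test_set:
            continue
        model = train(train_set, params=params, C=C, seed=seed, feature_cache=feature_cache)
        preds = [lab for lab, _ in predict(model, test_set, feature_cache=feature_cache)]
        counts = confusion([cd.label for cd in test_set], preds)
        per_fold.append(prf(*counts))
        totals = [t + c for t, c in zip(totals, counts)]
    return prf(*totals), per_fold


def cross_validate(
    corpus: Corpus,
    k: int = 10,
    params: KernelParams = KernelParams(),
    C: float = 1.0,
    seed: int = 0,
    feature_cache: FeatureCache | None = None,
) -> tuple[EvalResult, list[EvalResult]]:
    """Document-level k-fold CV.  Returns the pooled (micro-averaged) result
    computed from confusion counts summed over folds, plus per-fold results."""
    dataset = build_dataset(corpus)
    groups = _doc_groups(dataset)
    if feature_cache is None:
        feature_cache = build_feature_cache(dataset, params)
    return _cv_on_groups(groups, k, params, C, seed, feature_cache)


@dataclass(frozen=True)
class LearningCurvePoint:
    n_docs: int
    f_mean: float
    f_sd: float
    precision_mean: float
    precision_sd: float
    recall_mean: float
    recall_sd: float
    n_folds: int


def _mean_sd(xs: list[float]) -> tuple[float, float]:
    n = len(xs)
    mean = sum(xs) / n
    sd = math.sqrt(sum((x - mean) ** 2 for x in xs) / (n - 1)) if n > 1 else 0.0
    return mean, sd


def learning_curve(
    corpus: Corpus,
    sizes: Sequence[int] = DEFAULT_SIZE_LADDER,
    k: int = 10,
    repeats: int = 1,
    params: KernelParams = KernelParams(),
    C: float = 1.0,
    seed: int = 0,
) -> list[LearningCurvePoint]:
    """For each training-set size, sample that many documents without
    replacement, run document-level k-fold CV, and aggregate per-fold
    precision/recall/F as mean and sample SD (across folds and repeats).
    Sizes exceeding the corpus are skipped with a warning."""
    dataset = build_dataset(corpus)
    groups = _doc_groups(dataset)
    cache = build_feature_cache(dataset, params)
    all_ids = sorted(groups)
    points: list[LearningCurvePoint] = []
    for size in sizes:
        if size > len(all_ids):
            logger.warning("size %d exceeds corpus (%d documents); skipped", size, len(all_ids))
            continue
        fold_p: list[float] = []
        fold_r: list[float] = []
        fold_f: list[float] = []
        for rep in range(repeats):
            rng = random.Random((seed * 1_000_003 + size * 101 + rep) & 0x7FFFFFFF)
            chosen = rng.sample(all_ids, size)
            sub = {did: groups[did] for did in chosen}
            _, per_fold = _cv_on_groups(sub, min(k, size), params, C,
                                        seed=rng.randrange(2**31), feature_cache=cache)
            fold_p.extend(res.precision for res in per_fold)
            fold_r.extend(res.recall for res in per_fold)
            fold_f.extend(res.f_score for res in per_fold)
        pm, psd = _mean_sd(fold_p)
        rm, rsd = _mean_sd(fold_r)
        fm, fsd = _mean_sd(fold_f)
        points.append(
            LearningCurvePoint(
                n_docs=size, f_mean=fm, f_sd=fsd, precision_mean=pm, precision_sd=psd,
                recall_mean=rm, recall_sd=rsd, n_folds=len(fold_f),
            )
        )
    return points


def train_test_split_eval(
    corpus: Corpus,
    test_fraction: float = 0.1,
    params: KernelParams = KernelParams(),
    C: float = 1.0,
    seed: int = 0,
) -> EvalResult:
    """Held-out evaluation: split documents once, train on the remainder,
    report TRUE-class precision/recall/F on the held-out documents."""
    if not (0 < test_fraction < 1):
        raise ValueError("test_fraction must be in (0, 1)")
    dataset = build_dataset(corpus)
    groups = _doc_groups(dataset)
    ids = sorted(groups)
    rng = random.Random(seed)
    rng.shuffle(ids)
    n_test = max(1, round(len(ids) * test_fraction))
    test_ids = set(ids[:n_test])
    cache = build_feature_cache(dataset, params)
    train_set = [cd for did, cds in groups.items() if did not in test_ids for cd in cds]
    test_set = [cd for did in sorted(test_ids) for cd in groups[did]]
    model = train(train_set, params=params, C=C, seed=seed, feature_cache=cache)
    preds = [lab for lab, _ in predict(model, test_set, feature_cache=cache)]
    return prf(*confusion([cd.label for cd in test_set], preds))
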