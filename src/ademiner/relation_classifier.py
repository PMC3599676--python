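"""Binary SVM classification of relation candidates.

A linear SVM is trained on the explicit normalized feature map of the shallow
linguistic kernel; by the map/kernel dot-product equivalence this is the same
decision function a kernelized SVM with the summed normalized sub-kernels
would learn, but it scales to literature-sized candidate sets.  Models carry
their kernel parameters and refuse prediction under different ones.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import scipy.sparse as sp
from sklearn.feature_extraction import DictVectorizer
from sklearn.svm import LinearSVC

from .corpus_model import Label
from .instance_builder import RelationCandidate
from .slk_features import KernelParams, feature_map

_MODEL_FORMAT_VERSION = 1

FeatureCache = Mapping[str, Mapping[str, float]]


@dataclass
class TrainedModel:
    vectorizer: DictVectorizer
    svm: LinearSVC
    params: KernelParams
    C: float
    seed: int
    metadata: dict = field(default_factory=dict)


class SingleClassError(ValueError):
    pass


class ParamsMismatchError(ValueError):
    pass


class ModelFormatError(ValueError):
    pass


def _index32(X: sp.spmatrix) -> sp.csr_matrix:
    # liblinear requires 32-bit sparse indices
    X = sp.csr_matrix(X)
    X.indices = X.indices.astype(np.int32)
    X.indptr = X.indptr.astype(np.int32)
    return X


def _features(cands: Sequence[RelationCandidate], params: KernelParams,
              cache: FeatureCache | None) -> list[dict[str, float]]:
    out = []
    for cd in cands:
        if cache is not None and cd.instance_id in cache:
            out.append(dict(cache[cd.instance_id]))
        else:
            out.append(feature_map(cd, params).entries)
    return out


def train(
    dataset: Sequence[RelationCandidate],
    params: KernelParams = KernelParams(),
    C: float = 1.0,
    seed: int = 0,
    corpus_name: str = "",
    feature_cache: FeatureCache | None = None,
) -> TrainedModel:
    """Fit a linear SVM on the kernel's explicit feature map.

    The dataset is canonicalized by instance_id before fitting, so training is
    invariant to input shuffling.  ``feature_cache`` may supply precomputed
    feature maps keyed by instance_id (they must come from the same params).
    """
    if C <= 0:
        raise ValueError("C must be positive")
    labelled = sorted(dataset, key=lambda cd: cd.instance_id)
    labels = [cd.label for cd in labelled]
    if Label.UNKNOWN in labels:
        raise ValueError("dataset contains UNKNOWN labels; label candidates first")
    classes = set(labels)
    if classes != {Label.TRUE, Label.FALSE}:
        raise SingleClassError(f"training needs both classes, got {sorted(l.value for l in classes)}")
    feats = _features(labelled, params, feature_cache)
    y = [1 if l is Label.TRUE else 0 for l in labels]
    vectorizer = DictVectorizer(sparse=True)
    X = _index32(vectorizer.fit_transform(feats))
    svm = LinearSVC(C=C, random_state=seed, tol=1e-5, max_iter=20000)
    svm.fit(X, y)
    return TrainedModel(
        vectorizer=vectorizer,
        svm=svm,
        params=params,
        C=C,
        seed=seed,
        metadata={
            "corpus_name": corpus_name,
            "n_train": len(labelled),
            "trained_at": datetime.datetime.now(datetime.timezone.utc).isoformat(),
            "format_version": _MODEL_FORMAT_VERSION,
        },
    )


def predict(
    m: TrainedModel,
    cands: Sequence[RelationCandidate],
    params: KernelParams | None = None,
    feature_cache: FeatureCache | None = None,
) -> list[tuple[Label, float]]:
    """Label and margin score per candidate; TRUE iff score > 0 (a score of
    exactly 0 is conservatively FALSE)."""
    if params is not None and params != m.params:
        raise ParamsMismatchError(
            f"model was trained with {m.params}, prediction requested with {params}"
        )
    if not cands:
        return []
    X = _index32(m.vectorizer.transform(_features(cands, m.params, feature_cache)))
    scores = m.svm.decision_function(X)
    return [(Label.TRUE if s > 0 else Label.FALSE, float(s)) for s in scores]


def save_model(m: TrainedModel, path: str | Path) -> None:
    joblib.dump(
        {
            "format_version": _MODEL_FORMAT_VERSION,
            "vectorizer": m.vectorizer,
            "svm": m.svm,
            "params": {"n_max": m.params.n_max, "window": m.params.window,
                       "blind_entities": m.params.blind_entities},
            "C": m.C,
            "seed": m.seed,
            "metadata": m.metadata,
        },
        path,
    )


def load_model(path: str | Path) -> TrainedModel:
    try:
        payload = joblib.load(path)
    except Exception as exc:  # corrupted / not a joblib file
        raise ModelFormatError(f"{path}: cannot load model: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format_version") != _MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"{path}: unsupported model format "
            f"(version {payload.get('format_version') if isinstance(payload, dict) else '?'})"
        )
    return TrainedModel(
        vectorizer=payload["vectorizer"],
        svm=payload["svm"],
        params=KernelParams(**payload["params"]),
        C=payload["C"],
        seed=payload["seed"],
        metadata=payload["metadata"],
    )
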