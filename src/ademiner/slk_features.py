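"""Shallow linguistic kernel for relation candidates.

The similarity between two candidate drug-condition pairs is a sum of
normalized sub-kernels:

* three *global context* bag-of-n-gram kernels over lemma sequences drawn
  from the sentence segments around the candidate entities — fore-between
  (FB), between (B) and between-after (BA);
* one *local context* kernel (LC) over positional token features (surface
  form, lemma, POS tag, orthographic class) in a window around each
  candidate entity.

Each sub-kernel K_s is the dot product of sparse count vectors and is
cosine-normalized, K̂_s(a,b) = K_s(a,b)/sqrt(K_s(a,a)·K_s(b,b)) (defined as 0
when either self-similarity is 0), so the total kernel is bounded by the
number of non-empty sub-kernels (≤ 4).

Candidate entities are collapsed to single placeholder positions (DRUG_CAND /
COND_CAND when entity blinding is on, their head lemma sequence otherwise):
the fore-between segment is fore + [first entity] + between, the between
segment is strictly the tokens between the entities, and the between-after
segment is between + [second entity] + after, so n-grams may bridge a segment
boundary through the placeholder.

:func:`feature_map` is an explicit finite-dimensional map whose dot product
equals the kernel exactly, enabling linear-SVM training equivalent to the
kernel machine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .corpus_model import EntityMention, Token
from .instance_builder import RelationCandidate

NAMESPACES = ("FB", "B", "BA", "LC_LEFT", "LC_RIGHT")
SUBKERNELS = ("FB", "B", "BA", "LC")  # LC_LEFT + LC_RIGHT share one normalization

DRUG_PLACEHOLDER = "DRUG_CAND"
COND_PLACEHOLDER = "COND_CAND"


@dataclass(frozen=True)
class KernelParams:
    """n_max: longest n-gram in the global contexts; window: local-context
    half-width in token positions; blind_entities: replace candidate entity
    tokens with type placeholders."""

    n_max: int = 3
    window: int = 2
    blind_entities: bool = True

    def __post_init__(self) -> None:
        if self.n_max < 1:
            raise ValueError("n_max must be >= 1")
        if self.window < 0:
            raise ValueError("window must be >= 0")


@dataclass
class SparseFeatureVector:
    """Namespaced feature -> count map; keys are '<namespace>:<pattern>'."""

    entries: dict[str, float] = field(default_factory=dict)

    def add(self, key: str, count: float = 1.0) -> None:
        self.entries[key] = self.entries.get(key, 0.0) + count

    def merge(self, other: "SparseFeatureVector") -> "SparseFeatureVector":
        for k, v in other.entries.items():
            self.add(k, v)
        return self

    def restrict(self, namespace: str) -> dict[str, float]:
        prefix = namespace + ":"
        return {k: v for k, v in self.entries.items() if k.startswith(prefix)}

    def __len__(self) -> int:
        return len(self.entries)


class AnnotationMissingError(ValueError):
    pass


def _check_annotated(tokens: Iterable[Token]) -> None:
    for t in tokens:
        if not t.lemma or not t.pos:
            raise AnnotationMissingError(f"token {t.text!r} lacks lemma or POS annotation")


@dataclass(frozen=True)
class _Position:
    """One position of the collapsed sentence: either a plain token or a
    candidate-entity placeholder."""

    lemma: str
    text: str
    pos: str
    ortho: str
    is_entity: bool = False


def _collapse(cand: RelationCandidate, p: KernelParams) -> tuple[list[_Position], int, int]:
    """Collapse each candidate entity to one position; return the sequence and
    the positional indices of the first and second entity (sentence order)."""
    sent = cand.sentence
    _check_annotated(sent.tokens)
    first, second = sorted(
        (cand.drug, cand.condition), key=lambda m: (m.token_span.start, m.token_span.end)
    )

    # Non-candidate entity mentions keep their tokens; their entity flag is
    # exposed at the ortho level so local-context features can see it.
    other_etype: dict[int, str] = {}
    for m in sent.mentions:
        if m is cand.drug or m is cand.condition:
            continue
        for i in range(m.token_span.start, m.token_span.end):
            other_etype.setdefault(i, f"ENT_{m.etype.value}")

    def placeholder(m: EntityMention) -> _Position:
        if p.blind_entities:
            name = DRUG_PLACEHOLDER if m is cand.drug else COND_PLACEHOLDER
            return _Position(lemma=name, text=name, pos="ENT", ortho="ENT", is_entity=True)
        toks = sent.tokens[m.token_span.start : m.token_span.end]
        return _Position(
            lemma="_".join(t.lemma for t in toks),
            text="_".join(t.text for t in toks),
            pos=toks[-1].pos,
            ortho=toks[-1].ortho,
            is_entity=True,
        )

    def plain(i: int) -> _Position:
        t = sent.tokens[i]
        return _Position(lemma=t.lemma, text=t.text, pos=t.pos,
                         ortho=other_etype.get(i, t.ortho))

    seq: list[_Position] = []
    idx_first = idx_second = -1
    if first.token_span.overlaps(second.token_span):
        # Degenerate nested pair (survivor of nested-relation removal): the
        # two placeholders sit adjacent over the union span; between is empty.
        union = (min(first.token_span.start, second.token_span.start),
                 max(first.token_span.end, second.token_span.end))
        seq.extend(plain(i) for i in range(union[0]))
        idx_first = len(seq)
        seq.append(placeholder(first))
        idx_second = len(seq)
        seq.append(placeholder(second))
        seq.extend(plain(i) for i in range(union[1], len(sent.tokens)))
        return seq, idx_first, idx_second
    i = 0
    while i < len(sent.tokens):
        if i == first.token_span.start:
            idx_first = len(seq)
            seq.append(placeholder(first))
            i = first.token_span.end
        elif i == second.token_span.start:
            idx_second = len(seq)
            seq.append(placeholder(second))
            i = second.token_span.end
        else:
            seq.append(plain(i))
            i += 1
    return seq, idx_first, idx_second


def _ngrams(lemmas: list[str], n_max: int) -> Iterable[str]:
    for n in range(1, n_max + 1):
        for i in range(len(lemmas) - n + 1):
            yield "_".join(lemmas[i : i + n])


def global_context(cand: RelationCandidate, p: KernelParams) -> SparseFeatureVector:
    """FB, B and BA bag-of-n-gram features (lemma n-grams, n <= n_max)."""
    seq, i1, i2 = _collapse(cand, p)
    lem = [pos.lemma for pos in seq]
    fb = lem[: i1 + 1] + lem[i1 + 1 : i2]          # fore + first entity + between
    b = lem[i1 + 1 : i2]                            # strictly between
    ba = lem[i1 + 1 : i2 + 1] + lem[i2 + 1 :]       # between + second entity + after
    vec = SparseFeatureVector()
    for ns, segment in (("FB", fb), ("B", b), ("BA", ba)):
        for gram in _ngrams(segment, p.n_max):
            vec.add(f"{ns}:{gram}")
    return vec


_LC_ATTRS = ("text", "lemma", "pos", "ortho")


def local_context(cand: RelationCandidate, p: KernelParams) -> SparseFeatureVector:
    """Positional token features around each candidate entity.

    For each entity, positions r in [-window, +window] of the collapsed
    sequence (excluding the entity position itself) contribute one key per
    attribute in {text, lemma, pos, ortho}.  LC_LEFT covers the entity that
    occurs first in the sentence, LC_RIGHT the one that occurs second.
    """
    seq, i1, i2 = _collapse(cand, p)
    vec = SparseFeatureVector()
    for ns, center in (("LC_LEFT", i1), ("LC_RIGHT", i2)):
        for r in range(-p.window, p.window + 1):
            if r == 0:
                continue
            j = center + r
            if not (0 <= j < len(seq)):
                continue
            pos = seq[j]
            for attr in _LC_ATTRS:
                vec.add(f"{ns}:{r}:{attr}:{getattr(pos, attr)}")
    return vec


def featurize(cand: RelationCandidate, p: KernelParams) -> SparseFeatureVector:
    """All five namespaces in one sparse vector (raw counts, unnormalized)."""
    return global_context(cand, p).merge(local_context(cand, p))


def _subkernel_entries(vec: SparseFeatureVector, sub: str) -> dict[str, float]:
    if sub == "LC":
        return {**vec.restrict("LC_LEFT"), **vec.restrict("LC_RIGHT")}
    return vec.restrict(sub)


def _dot(a: Mapping[str, float], b: Mapping[str, float]) -> float:
    if len(b) < len(a):
        a, b = b, a
    # canonical summation order makes kernel(a, b) == kernel(b, a) bit-exact
    return sum(a[k] * b[k] for k in sorted(k for k in a if k in b))


def kernel(a: RelationCandidate, b: RelationCandidate, p: KernelParams) -> float:
    """Sum of cosine-normalized sub-kernel similarities; in [0, 4]."""
    va, vb = featurize(a, p), featurize(b, p)
    total = 0.0
    for sub in SUBKERNELS:
        ea, eb = _subkernel_entries(va, sub), _subkernel_entries(vb, sub)
        saa, sbb = _dot(ea, ea), _dot(eb, eb)
        if saa == 0.0 or sbb == 0.0:
            continue
        total += _dot(ea, eb) / math.sqrt(saa * sbb)
    return total


def feature_map(cand: RelationCandidate, p: KernelParams) -> SparseFeatureVector:
    """Explicit map x with dot(x_a, x_b) = kernel(a, b) in exact arithmetic:
    each sub-kernel's block is scaled by 1/sqrt(K_s(x,x))."""
    raw = featurize(cand, p)
    out = SparseFeatureVector()
    for sub in SUBKERNELS:
        entries = _subkernel_entries(raw, sub)
        norm = math.sqrt(_dot(entries, entries))
        if norm == 0.0:
            continue
        for k, v in entries.items():
            out.entries[k] = v / norm
    return out
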