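"""Dataset construction: sentence-level drug-condition candidate pairs.

Every drug mention paired with every condition mention in the same sentence
forms a relation candidate.  Candidates matching a gold adverse event relation
are labelled TRUE; all remaining co-occurrences are FALSE — the automatic
negative instances that make supervised training possible on a corpus where
only positive relations were hand-annotated.  Gold relations whose drug and
condition spans overlap (a drug name nested inside a condition phrase, e.g.
"lithium" inside "acute lithium toxicity") are not usable sentence-level
instances and are removed first.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

from .corpus_model import (
    Corpus,
    EntityMention,
    EntityType,
    Label,
    Sentence,
)


@dataclass
class RelationCandidate:
    """An ordered (drug mention, condition mention) pair within one sentence."""

    doc_id: str
    sid: str
    sentence: Sentence
    drug: EntityMention
    condition: EntityMention
    label: Label = Label.UNKNOWN
    instance_id: str = ""

    def __post_init__(self) -> None:
        if self.drug.etype is not EntityType.DRUG:
            raise ValueError(f"candidate drug mention has etype {self.drug.etype.value}")
        if self.condition.etype is not EntityType.CONDITION:
            raise ValueError(
                f"candidate condition mention has etype {self.condition.etype.value}"
            )
        if not self.instance_id:
            self.instance_id = (
                f"{self.doc_id}:{self.sid}:"
                f"d{self.drug.char_span.start}-c{self.condition.char_span.start}"
            )


def enumerate_candidates(s: Sentence, doc_id: str = "") -> list[RelationCandidate]:
    """All |drugs| x |conditions| pairs of a sentence, label UNKNOWN, ordered
    by (drug char start, condition char start)."""
    drugs = sorted(s.mentions_of(EntityType.DRUG), key=lambda m: (m.char_span.start, m.char_span.end))
    conds = sorted(
        s.mentions_of(EntityType.CONDITION), key=lambda m: (m.char_span.start, m.char_span.end)
    )
    return [
        RelationCandidate(doc_id=doc_id, sid=s.sid, sentence=s, drug=dm, condition=cm)
        for dm in drugs
        for cm in conds
    ]


class GoldConsistencyError(ValueError):
    pass


def _gold_pairs(c: Corpus) -> dict[str, set[tuple]]:
    """Per-document set of gold (sid, drug char span, condition char span)."""
    out: dict[str, set[tuple]] = {}
    for d in c.documents:
        pairs = set()
        for rel in d.gold_relations:
            sent = d.sentence(rel.sid)
            dm, cm = sent.mentions[rel.drug_idx], sent.mentions[rel.cond_idx]
            pairs.add((rel.sid, dm.char_span, cm.char_span))
        out[d.doc_id] = pairs
    return out


def label_candidates(
    cands: list[RelationCandidate], gold: set[tuple]
) -> list[RelationCandidate]:
    """Label each candidate TRUE if its (sid, drug span, condition span) is in
    ``gold``, else FALSE.  Every gold pair must match some candidate."""
    keys = {(cd.sid, cd.drug.char_span, cd.condition.char_span) for cd in cands}
    missing = gold - keys
    if missing:
        raise GoldConsistencyError(f"gold pairs with no matching candidate: {sorted(missing)[:5]}")
    for cd in cands:
        key = (cd.sid, cd.drug.char_span, cd.condition.char_span)
        cd.label = Label.TRUE if key in gold else Label.FALSE
    return cands


def remove_nested(c: Corpus) -> tuple[Corpus, int]:
    """Drop gold relations whose drug and condition character spans overlap
    (this covers full containment as a special case).  Mentions themselves
    are kept.  Returns the cleaned corpus and the number of relations removed."""
    c = copy.deepcopy(c)
    removed = 0
    for d in c.documents:
        kept = []
        for rel in d.gold_relations:
            sent = d.sentence(rel.sid)
            dm, cm = sent.mentions[rel.drug_idx], sent.mentions[rel.cond_idx]
            if dm.char_span.overlaps(cm.char_span):
                removed += 1
            else:
                kept.append(rel)
        d.gold_relations = kept
    return c, removed


def build_dataset(c: Corpus, drop_nested: bool = True) -> list[RelationCandidate]:
    """remove_nested -> enumerate -> label, over all sentences of the corpus.

    Deterministic: candidates ordered by (document order, sentence order,
    drug offset, condition offset); instance ids derived from offsets.
    """
    if drop_nested:
        c, _ = remove_nested(c)
    gold = _gold_pairs(c)
    dataset: list[RelationCandidate] = []
    for d in c.documents:
        cands = [cd for s in d.sentences for cd in enumerate_candidates(s, doc_id=d.doc_id)]
        dataset.extend(label_candidates(cands, gold[d.doc_id]))
    return dataset
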