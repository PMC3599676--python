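"""Shared fixtures: hand-built sentences and seeded synthetic corpora."""

from __future__ import annotations

import pytest

from ademiner.corpus_model import (
    Corpus,
    Document,
    EntityMention,
    EntityType,
    GoldRelation,
    Provenance,
    Sentence,
    Span,
    default_annotator,
    token_span_for_chars,
)
from ademiner.instance_builder import RelationCandidate, build_dataset
from ademiner.lexicon_ner import annotate_corpus
from ademiner.synthetic_corpus import GeneratorConfig, generate, make_lexicons


def make_sentence(
    text: str,
    mentions: list[tuple[int, int, EntityType]] | None = None,
    sid: str = "s0",
    provenance: Provenance = Provenance.HUMAN,
) -> Sentence:
    """Sentence with tokens from the default annotator and mentions given as
    (char start, char end, entity type) triples."""
    sent = Sentence(sid=sid, text=text, tokens=default_annotator(text))
    for start, end, etype in mentions or []:
        span = Span(start, end)
        sent.mentions.append(
            EntityMention(
                etype=etype,
                token_span=token_span_for_chars(sent.tokens, span),
                char_span=span,
                provenance=provenance,
            )
        )
    return sent


def make_candidate(
    text: str,
    drug_span: tuple[int, int],
    cond_span: tuple[int, int],
    doc_id: str = "d0",
    sid: str = "s0",
) -> RelationCandidate:
    sent = make_sentence(
        text,
        [(drug_span[0], drug_span[1], EntityType.DRUG),
         (cond_span[0], cond_span[1], EntityType.CONDITION)],
        sid=sid,
    )
    return RelationCandidate(
        doc_id=doc_id, sid=sid, sentence=sent,
        drug=sent.mentions[0], condition=sent.mentions[1],
    )


def one_sentence_corpus(sent: Sentence, relations: list[tuple[int, int]] | None = None,
                        doc_id: str = "d0") -> Corpus:
    doc = Document(
        doc_id=doc_id,
        sentences=[sent],
        gold_relations=[GoldRelation(sid=sent.sid, drug_idx=d, cond_idx=c)
                        for d, c in relations or []],
    )
    return Corpus(documents=[doc], name="tiny")


@pytest.fixture(scope="session")
def small_synth():
    """50 documents, no noise, everything human-annotated: labels in the
    corpus equal the generator's planted labels exactly."""
    cfg = GeneratorConfig(n_docs=50, noise_rate=0.0, unannotated_rate=0.0, seed=11)
    return generate(cfg)


@pytest.fixture(scope="session")
def annotated_synth():
    """60 documents with a third of distractor mentions initially unannotated,
    then recovered by dictionary NER — the full corpus-preparation pipeline."""
    cfg = GeneratorConfig(n_docs=60, noise_rate=0.0, unannotated_rate=0.3, seed=23)
    corpus, ledger = generate(cfg)
    dlex, clex = make_lexicons(ledger)
    corpus = annotate_corpus(corpus, dlex, clex)
    return corpus, ledger


@pytest.fixture(scope="session")
def synth_dataset(annotated_synth):
    corpus, _ = annotated_synth
    return build_dataset(corpus)
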