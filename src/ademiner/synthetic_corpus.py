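"""Synthetic annotated case-report corpora with controllable signal.

Emulates the statistical shape of a sentence-level adverse event corpus:
short case-report-like sentences, sparse gold drug-condition relations,
distractor co-occurrences that form negative candidates, a configurable
fraction of mentions left unannotated (to exercise dictionary NER), nested
drug-in-condition annotations, and label noise.

Sentences are built from templates.  *Trigger* templates carry a causal cue
("induced", "caused", "was attributed to") in the segment between the two
entities, so the deciding signal is reachable by between-segment n-grams of
the shallow linguistic kernel; *distractor* templates co-mention a drug and a
condition without the cue.  Every planted pair, mention and identifier is
recorded in a generation ledger — the single source of expected values for
tests of the downstream pipeline.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .corpus_model import (
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
from .lexicon_ner import Lexicon

_SYLLABLES = (
    "zan", "bet", "cor", "dal", "fex", "gri", "hep", "jun", "kel", "mor",
    "nis", "pol", "quil", "rov", "sab", "tem", "vur", "wex", "yol", "zam",
)
_DRUG_SUFFIXES = ("ib", "ol", "ide", "ine", "umab", "axin")
_COND_SUFFIXES = ("itis", "osis", "emia", "algia", "pathy", "oma")
_COND_MODIFIERS = ("", "", "severe ", "chronic ", "recurrent ")


@dataclass(frozen=True)
class Template:
    """Token sequence with {DRUG}/{DRUG2}/{COND}/{COND2} slots and the planted
    label of each (drug slot, condition slot) pair."""

    tokens: tuple[str, ...]
    pair_labels: tuple[tuple[str, str, bool], ...]  # (drug_slot, cond_slot, is_true)
    nested: bool = False


TRIGGER_TEMPLATES: tuple[Template, ...] = (
    Template(("Treatment", "with", "{DRUG}", "induced", "{COND}", "in", "the", "patient", "."),
             (("{DRUG}", "{COND}", True),)),
    Template(("The", "patient", "developed", "{COND}", "after", "{DRUG}", "therapy", "."),
             (("{DRUG}", "{COND}", True),)),
    Template(("{DRUG}", "caused", "{COND}", "during", "the", "second", "week", "."),
             (("{DRUG}", "{COND}", True),)),
    Template(("{COND}", "was", "attributed", "to", "{DRUG}", "exposure", "."),
             (("{DRUG}", "{COND}", True),)),
    Template(("{DRUG}", "induced", "{COND}", "and", "{COND2}", "within", "days", "."),
             (("{DRUG}", "{COND}", True), ("{DRUG}", "{COND2}", True))),
    Template(("{DRUG}", "induced", "{COND}", "but", "not", "{COND2}", "in", "this", "case", "."),
             (("{DRUG}", "{COND}", True), ("{DRUG}", "{COND2}", False))),
)

DISTRACTOR_TEMPLATES: tuple[Template, ...] = (
    Template(("The", "patient", "received", "{DRUG}", "and", "had", "a", "history", "of",
              "{COND}", "."),
             (("{DRUG}", "{COND}", False),)),
    Template(("{DRUG}", "was", "administered", "while", "{COND}", "remained", "stable", "."),
             (("{DRUG}", "{COND}", False),)),
    Template(("Preexisting", "{COND}", "was", "documented", "before", "{DRUG}",
              "administration", "."),
             (("{DRUG}", "{COND}", False),)),
    Template(("{DRUG}", "and", "{DRUG2}", "were", "given", "for", "unrelated", "{COND}", "."),
             (("{DRUG}", "{COND}", False), ("{DRUG2}", "{COND}", False))),
)

# Gold relation between a drug and a condition phrase that contains the drug
# name; dropped by nested-annotation removal.
NESTED_TEMPLATE = Template(
    ("Acute", "{DRUG}", "toxicity", "required", "hospital", "admission", "."),
    (("{DRUG}", "NESTED_COND", True),),
    nested=True,
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Defaults mirror the shape of an extended adverse event corpus: ~3
    candidate-bearing sentences per document, a TRUE:FALSE planted-pair ratio
    near 55:45, ~2% nested gold relations, and roughly a third of distractor
    mentions left for dictionary NER to recover."""

    n_docs: int = 100
    sentences_per_doc: int = 3
    p_true: float = 0.55
    noise_rate: float = 0.0
    unannotated_rate: float = 0.3
    nested_rate: float = 0.02
    n_drug_vocab: int = 100
    n_cond_vocab: int = 120
    seed: int = 0
    trigger_templates: tuple[Template, ...] = TRIGGER_TEMPLATES
    distractor_templates: tuple[Template, ...] = DISTRACTOR_TEMPLATES

    def __post_init__(self) -> None:
        for rate in (self.p_true, self.noise_rate, self.unannotated_rate, self.nested_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if not self.trigger_templates or not self.distractor_templates:
            raise ValueError("need at least one trigger and one distractor template")


@dataclass(frozen=True)
class PlantedPair:
    doc_id: str
    sid: str
    drug_span: Span
    cond_span: Span
    drug_id: str
    cond_id: str | None
    label: bool  # planted gold membership AFTER label noise
    nested: bool = False
    flipped: bool = False


@dataclass(frozen=True)
class PlantedMention:
    doc_id: str
    sid: str
    etype: EntityType
    char_span: Span
    surface: str
    norm_id: str
    annotated: bool  # False: left for dictionary NER


@dataclass
class GenerationLedger:
    """Ground truth of a generation run: every planted pair and mention plus
    the vocabularies with their synthetic identifiers."""

    pairs: list[PlantedPair] = field(default_factory=list)
    mentions: list[PlantedMention] = field(default_factory=list)
    drug_vocab: dict[str, str] = field(default_factory=dict)   # surface -> id
    cond_vocab: dict[str, str] = field(default_factory=dict)

    @property
    def n_true(self) -> int:
        return sum(1 for p in self.pairs if p.label and not p.nested)

    @property
    def n_false(self) -> int:
        return sum(1 for p in self.pairs if not p.label)

    @property
    def n_nested(self) -> int:
        return sum(1 for p in self.pairs if p.nested)

    @property
    def unannotated(self) -> list[PlantedMention]:
        return [m for m in self.mentions if not m.annotated]


def _make_vocab(n: int, suffixes: tuple[str, ...], id_prefix: str,
                modifiers: tuple[str, ...] = ("",)) -> dict[str, str]:
    vocab: dict[str, str] = {}
    i = 0
    while len(vocab) < n:
        s1 = _SYLLABLES[i % len(_SYLLABLES)]
        s2 = _SYLLABLES[(i // len(_SYLLABLES)) % len(_SYLLABLES)]
        suffix = suffixes[i % len(suffixes)]
        modifier = modifiers[(i // 7) % len(modifiers)]
        surface = f"{modifier}{s1}{s2}{suffix}"
        if surface not in vocab:
            vocab[surface] = f"{id_prefix}{len(vocab):05d}"
        i += 1
    return vocab


def generate(cfg: GeneratorConfig) -> tuple[Corpus, GenerationLedger]:
    """Generate a corpus and its ground-truth ledger, deterministically under
    ``cfg.seed``."""
    rng = random.Random(cfg.seed)
    ledger = GenerationLedger(
        drug_vocab=_make_vocab(cfg.n_drug_vocab, _DRUG_SUFFIXES, "D"),
        cond_vocab=_make_vocab(cfg.n_cond_vocab, _COND_SUFFIXES, "C", _COND_MODIFIERS),
    )
    drug_surfaces = list(ledger.drug_vocab)
    cond_surfaces = list(ledger.cond_vocab)
    documents = []
    for di in range(cfg.n_docs):
        doc_id = str(10_000_000 + di)
        sentences: list[Sentence] = []
        relations: list[GoldRelation] = []
        for sj in range(cfg.sentences_per_doc):
            sid = f"s{sj}"
            if rng.random() < cfg.nested_rate:
                template = NESTED_TEMPLATE
            elif rng.random() < cfg.p_true:
                template = rng.choice(cfg.trigger_templates)
            else:
                template = rng.choice(cfg.distractor_templates)
            slots = sorted({slot for a, b, _ in template.pair_labels for slot in (a, b)
                            if slot != "NESTED_COND"})
            fills: dict[str, tuple[str, str, EntityType]] = {}
            for slot in slots:
                if slot.startswith("{DRUG"):
                    surface = rng.choice(drug_surfaces)
                    fills[slot] = (surface, ledger.drug_vocab[surface], EntityType.DRUG)
                else:
                    surface = rng.choice(cond_surfaces)
                    fills[slot] = (surface, ledger.cond_vocab[surface], EntityType.CONDITION)
            # flip planted labels with the configured noise before deciding
            # which mentions must stay human-annotated (gold participants do)
            pair_plan: list[tuple[str, str, bool, bool]] = []
            for drug_slot, cond_slot, is_true in template.pair_labels:
                flipped = (not template.nested) and rng.random() < cfg.noise_rate
                pair_plan.append((drug_slot, cond_slot, bool(is_true ^ flipped), flipped))
            # lay out the sentence text, tracking slot character spans
            words: list[str] = []
            cursor = 0
            slot_spans: dict[str, Span] = {}
            for tok in template.tokens:
                text_piece = fills[tok][0] if tok in fills else tok
                start = cursor
                words.append(text_piece)
                cursor += len(text_piece)
                if tok in fills:
                    slot_spans[tok] = Span(start, cursor)
                cursor += 1  # single space
            text = " ".join(words)
            sent = Sentence(sid=sid, text=text, tokens=default_annotator(text))
            mentions: list[EntityMention] = []
            mention_idx: dict[str, int] = {}
            in_gold = {slot for a, b, lab, _ in pair_plan for slot in (a, b) if lab}
            for slot in slots:
                surface, norm_id, etype = fills[slot]
                char_span = slot_spans[slot]
                annotated = slot in in_gold or rng.random() >= cfg.unannotated_rate
                ledger.mentions.append(
                    PlantedMention(doc_id=doc_id, sid=sid, etype=etype, char_span=char_span,
                                   surface=surface, norm_id=norm_id, annotated=annotated)
                )
                if annotated:
                    mention_idx[slot] = len(mentions)
                    mentions.append(
                        EntityMention(etype=etype,
                                      token_span=token_span_for_chars(sent.tokens, char_span),
                                      char_span=char_span, norm_id=norm_id,
                                      provenance=Provenance.HUMAN)
                    )
            if template.nested:
                # condition phrase "Acute <drug> toxicity" containing the drug
                drug_span = slot_spans["{DRUG}"]
                cond_span = Span(0, drug_span.end + len(" toxicity"))
                mention_idx["NESTED_COND"] = len(mentions)
                mentions.append(
                    EntityMention(etype=EntityType.CONDITION,
                                  token_span=token_span_for_chars(sent.tokens, cond_span),
                                  char_span=cond_span, norm_id=None,
                                  provenance=Provenance.HUMAN)
                )
            sent.mentions = mentions
            sentences.append(sent)
            for drug_slot, cond_slot, label, flipped in pair_plan:
                drug_id = fills[drug_slot][1]
                if cond_slot == "NESTED_COND":
                    cond_span, cond_id = mentions[mention_idx["NESTED_COND"]].char_span, None
                else:
                    cond_span, cond_id = slot_spans[cond_slot], fills[cond_slot][1]
                if label:
                    relations.append(
                        GoldRelation(sid=sid, drug_idx=mention_idx[drug_slot],
                                     cond_idx=mention_idx[cond_slot])
                    )
                ledger.pairs.append(
                    PlantedPair(doc_id=doc_id, sid=sid, drug_span=slot_spans[drug_slot],
                                cond_span=cond_span, drug_id=drug_id, cond_id=cond_id,
                                label=bool(label), nested=template.nested, flipped=flipped)
                )
        documents.append(Document(doc_id=doc_id, sentences=sentences, gold_relations=relations))
    corpus = Corpus(documents=documents, name=f"synthetic-{cfg.n_docs}docs-seed{cfg.seed}")
    corpus.validate()
    return corpus, ledger


def make_lexicons(ledger: GenerationLedger) -> tuple[Lexicon, Lexicon]:
    """Drug and condition lexicons covering exactly the generator vocabularies."""
    return (
        Lexicon(etype=EntityType.DRUG, entries=dict(ledger.drug_vocab), name="drugbank-like"),
        Lexicon(etype=EntityType.CONDITION, entries=dict(ledger.cond_vocab), name="meddra-like"),
    )


def write_lexicon_tsv(lex: Lexicon, path: str | Path) -> None:
    lines = [f"{term}\t{ident}" for term, ident in sorted(lex.entries.items())]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
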