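"""Domain model for annotated case-report corpora.

A :class:`Corpus` holds documents of sentences; each sentence carries tokens
(with lemma, part-of-speech tag and orthographic class) and typed entity
mentions (drugs and conditions) located by character offsets.  Gold adverse
event relations connect a drug mention and a condition mention inside one
sentence.  All character spans are 0-based, half-open, relative to the
sentence text.

Two serialisations are provided:

* a standoff JSON dialect (one object per document, explicit character
  offsets) — the corpus interchange format;
* the line-oriented SRE instance format used by shallow-linguistic-kernel
  relation extractors, where each token is enriched with its lemma, POS tag,
  entity flag and candidate role.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Sequence


class EntityType(str, Enum):
    DRUG = "DRUG"
    CONDITION = "CONDITION"


class Provenance(str, Enum):
    HUMAN = "HUMAN"
    MACHINE = "MACHINE"


class Label(str, Enum):
    TRUE = "TRUE"
    FALSE = "FALSE"
    UNKNOWN = "UNKNOWN"


class CorpusFormatError(ValueError):
    """Raised when a serialized corpus or SRE file cannot be parsed."""


class CorpusValidationError(ValueError):
    """Raised when parsed content violates a domain invariant."""


@dataclass(frozen=True, order=True)
class Span:
    """Half-open 0-based interval [start, end)."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CorpusValidationError(f"invalid span [{self.start}, {self.end})")

    def overlaps(self, other: "Span") -> bool:
        return self.start < other.end and other.start < self.end

    def contains(self, other: "Span") -> bool:
        return self.start <= other.start and other.end <= self.end

    def __len__(self) -> int:
        return self.end - self.start


# Orthographic classes
ORTHO_CLASSES = ("ALPHA_LOWER", "ALPHA_CAP", "ALPHA_MIXED", "DIGIT", "ALNUM", "PUNCT", "OTHER")


def ortho_class(text: str) -> str:
    if text.isalpha():
        if text.islower():
            return "ALPHA_LOWER"
        if len(text) >= 1 and text[0].isupper() and text[1:].islower():
            return "ALPHA_CAP"
        return "ALPHA_MIXED"
    if text.isdigit():
        return "DIGIT"
    if text.isalnum():
        return "ALNUM"
    if all(not ch.isalnum() and not ch.isspace() for ch in text):
        return "PUNCT"
    return "OTHER"


@dataclass(frozen=True)
class Token:
    text: str
    lemma: str
    pos: str
    ortho: str
    span: Span


@dataclass(frozen=True)
class EntityMention:
    etype: EntityType
    token_span: Span  # token-index interval, half-open
    char_span: Span
    norm_id: str | None = None
    provenance: Provenance = Provenance.HUMAN


@dataclass
class Sentence:
    sid: str
    text: str
    tokens: list[Token] = field(default_factory=list)
    mentions: list[EntityMention] = field(default_factory=list)

    def mentions_of(self, etype: EntityType) -> list[EntityMention]:
        return [m for m in self.mentions if m.etype is etype]

    def validate(self) -> None:
        prev_end = -1
        for tok in self.tokens:
            if tok.span.start < prev_end:
                raise CorpusValidationError(
                    f"sentence {self.sid!r}: tokens overlap or out of order at {tok.span}"
                )
            if tok.span.end > len(self.text):
                raise CorpusValidationError(
                    f"sentence {self.sid!r}: token span {tok.span} exceeds text length {len(self.text)}"
                )
            if self.text[tok.span.start : tok.span.end] != tok.text:
                raise CorpusValidationError(
                    f"sentence {self.sid!r}: token text {tok.text!r} does not match span {tok.span}"
                )
            prev_end = tok.span.end
        for m in self.mentions:
            if m.char_span.end > len(self.text):
                raise CorpusValidationError(
                    f"sentence {self.sid!r}: mention span {m.char_span} exceeds text length {len(self.text)}"
                )
            if len(m.token_span) < 1:
                raise CorpusValidationError(f"sentence {self.sid!r}: empty mention token span")
            if m.token_span.end > len(self.tokens):
                raise CorpusValidationError(
                    f"sentence {self.sid!r}: mention token span {m.token_span} exceeds token count"
                )
            covered = [self.tokens[i].span for i in range(m.token_span.start, m.token_span.end)]
            for pos in range(m.char_span.start, m.char_span.end):
                if self.text[pos].isspace():
                    continue
                if not any(sp.start <= pos < sp.end for sp in covered):
                    raise CorpusValidationError(
                        f"sentence {self.sid!r}: mention char span {m.char_span} not covered by its tokens"
                    )
        # Same-provenance, same-type mentions must not overlap.  Cross-type
        # overlap of HUMAN mentions is allowed: nested annotations (a drug
        # name inside a condition phrase) occur in real corpora and are what
        # nested-relation removal operates on.
        for prov in (Provenance.HUMAN, Provenance.MACHINE):
            for etype in EntityType:
                same = sorted(
                    (m.char_span for m in self.mentions
                     if m.provenance is prov and m.etype is etype),
                    key=lambda s: (s.start, s.end),
                )
                for a, b in zip(same, same[1:]):
                    if a.overlaps(b):
                        raise CorpusValidationError(
                            f"sentence {self.sid!r}: overlapping {prov.value} "
                            f"{etype.value} mentions {a} and {b}"
                        )


@dataclass(frozen=True)
class GoldRelation:
    """A gold adverse event relation: indices into a sentence's mention list."""

    sid: str
    drug_idx: int
    cond_idx: int


@dataclass
class Document:
    doc_id: str
    sentences: list[Sentence] = field(default_factory=list)
    gold_relations: list[GoldRelation] = field(default_factory=list)

    def sentence(self, sid: str) -> Sentence:
        for s in self.sentences:
            if s.sid == sid:
                return s
        raise KeyError(f"document {self.doc_id!r} has no sentence {sid!r}")

    def validate(self) -> None:
        sids = [s.sid for s in self.sentences]
        if len(set(sids)) != len(sids):
            raise CorpusValidationError(f"document {self.doc_id!r}: duplicate sentence ids")
        for s in self.sentences:
            s.validate()
        for rel in self.gold_relations:
            try:
                sent = self.sentence(rel.sid)
            except KeyError as exc:
                raise CorpusValidationError(
                    f"document {self.doc_id!r}: relation references unknown sentence {rel.sid!r}"
                ) from exc
            for idx, want in ((rel.drug_idx, EntityType.DRUG), (rel.cond_idx, EntityType.CONDITION)):
                if not (0 <= idx < len(sent.mentions)):
                    raise CorpusValidationError(
                        f"document {self.doc_id!r}: relation mention index {idx} out of range "
                        f"in sentence {rel.sid!r}"
                    )
                if sent.mentions[idx].etype is not want:
                    raise CorpusValidationError(
                        f"document {self.doc_id!r}: relation expects {want.value} at index {idx} "
                        f"in sentence {rel.sid!r}, found {sent.mentions[idx].etype.value}"
                    )


@dataclass
class Corpus:
    documents: list[Document] = field(default_factory=list)
    name: str = "corpus"

    def validate(self) -> None:
        ids = [d.doc_id for d in self.documents]
        if len(set(ids)) != len(ids):
            raise CorpusValidationError(f"corpus {self.name!r}: duplicate doc_ids")
        for d in self.documents:
            d.validate()


# ---------------------------------------------------------------------------
# Annotation: tokenizer + POS tagger + lemmatizer
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\w+|[^\w\s]", re.UNICODE)

# Small closed-class tables for the coarse heuristic tagger.
_DETS = {"a", "an", "the", "this", "that", "these", "those"}
_ADPS = {"of", "in", "on", "at", "by", "with", "from", "to", "after", "before",
         "during", "following", "under", "over", "without", "for"}
_CONJS = {"and", "or", "but", "while", "whereas"}
_PRONS = {"he", "she", "it", "they", "we", "i", "you", "her", "his", "their"}
_AUX = {"is", "was", "were", "are", "be", "been", "being", "had", "has", "have", "did", "does", "do"}
_VERB_SUFFIXES = ("ed", "ing", "ize", "ise", "ates")
_ADJ_SUFFIXES = ("ous", "ic", "al", "ive", "able", "ible", "severe", "acute", "mild")


def pos_tag(word: str) -> str:
    """Coarse deterministic POS heuristic over a single token."""
    low = word.lower()
    if not any(ch.isalnum() for ch in word):
        return "PUNCT"
    if word.isdigit():
        return "NUM"
    if low in _DETS:
        return "DET"
    if low in _ADPS:
        return "ADP"
    if low in _CONJS:
        return "CCONJ"
    if low in _PRONS:
        return "PRON"
    if low in _AUX:
        return "AUX"
    if low.endswith("ly"):
        return "ADV"
    if low.endswith(_VERB_SUFFIXES):
        return "VERB"
    if low.endswith(_ADJ_SUFFIXES) or low in ("severe", "acute", "mild", "chronic"):
        return "ADJ"
    return "NOUN"


def lemmatize(word: str) -> str:
    """Lower-case the token and strip a trivial plural suffix."""
    low = word.lower()
    if len(low) > 3 and low.endswith("ies"):
        return low[:-3] + "y"
    if len(low) > 3 and low.endswith("s") and not low.endswith(("ss", "us", "is")):
        return low[:-1]
    return low


Annotator = Callable[[str], list[Token]]


def default_annotator(text: str) -> list[Token]:
    """Deterministic bundled annotator: split on whitespace/punctuation,
    tag and lemmatize with rule tables.  Pluggable: any callable with this
    signature may replace it throughout the package."""
    tokens: list[Token] = []
    for m in _TOKEN_RE.finditer(text):
        word = m.group(0)
        tokens.append(
            Token(
                text=word,
                lemma=lemmatize(word),
                pos=pos_tag(word),
                ortho=ortho_class(word),
                span=Span(m.start(), m.end()),
            )
        )
    return tokens


def token_span_for_chars(tokens: Sequence[Token], char_span: Span) -> Span:
    """Token-index interval of the tokens overlapping ``char_span``."""
    idx = [i for i, t in enumerate(tokens) if t.span.overlaps(char_span)]
    if not idx:
        raise CorpusValidationError(f"no tokens overlap char span {char_span}")
    return Span(idx[0], idx[-1] + 1)


# ---------------------------------------------------------------------------
# Standoff JSON reader / writer
# ---------------------------------------------------------------------------

STANDOFF_JSON = "STANDOFF_JSON"


def _mention_from_json(obj: dict, sent: Sentence, doc_id: str) -> EntityMention:
    try:
        etype = EntityType(obj["etype"])
        start, end = int(obj["start"]), int(obj["end"])
    except (KeyError, ValueError) as exc:
        raise CorpusFormatError(f"doc {doc_id!r}: malformed mention record {obj!r}") from exc
    if not (0 <= start < end <= len(sent.text)):
        raise CorpusValidationError(
            f"doc {doc_id!r} sentence {sent.sid!r}: mention offsets [{start}, {end}) "
            f"outside text of length {len(sent.text)}"
        )
    char_span = Span(start, end)
    prov = Provenance(obj.get("provenance", "HUMAN"))
    return EntityMention(
        etype=etype,
        token_span=token_span_for_chars(sent.tokens, char_span),
        char_span=char_span,
        norm_id=obj.get("norm_id"),
        provenance=prov,
    )


def read_corpus(path: str | Path, fmt: str = STANDOFF_JSON,
                annotator: Annotator = default_annotator) -> Corpus:
    """Read a corpus from the standoff JSON dialect.

    The file is a JSON object ``{"name": ..., "documents": [...]}`` (or a bare
    list of documents).  Sentences are tokenized with ``annotator`` on read;
    offsets are validated against the sentence text.
    """
    if fmt != STANDOFF_JSON:
        raise ValueError(f"unsupported corpus format {fmt!r}")
    path = Path(path)
    try:
        payload = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise CorpusFormatError(f"{path}: not valid JSON: {exc}") from exc
    if isinstance(payload, dict):
        name = payload.get("name", path.stem)
        docs_json = payload.get("documents", [])
    else:
        name, docs_json = path.stem, payload
    documents = []
    for dj in docs_json:
        try:
            doc_id = str(dj["doc_id"])
        except (TypeError, KeyError) as exc:
            raise CorpusFormatError(f"{path}: document record missing doc_id: {dj!r}") from exc
        sentences = []
        for sj in dj.get("sentences", []):
            try:
                sid, text = str(sj["sid"]), sj["text"]
            except (TypeError, KeyError) as exc:
                raise CorpusFormatError(
                    f"doc {doc_id!r}: sentence record missing sid/text"
                ) from exc
            sent = Sentence(sid=sid, text=text, tokens=annotator(text))
            sent.mentions = [_mention_from_json(mj, sent, doc_id) for mj in sj.get("mentions", [])]
            sentences.append(sent)
        relations = []
        for rj in dj.get("relations", []):
            try:
                relations.append(
                    GoldRelation(sid=str(rj["sid"]), drug_idx=int(rj["drug_idx"]),
                                 cond_idx=int(rj["cond_idx"]))
                )
            except (TypeError, KeyError, ValueError) as exc:
                raise CorpusFormatError(f"doc {doc_id!r}: malformed relation {rj!r}") from exc
        documents.append(Document(doc_id=doc_id, sentences=sentences, gold_relations=relations))
    corpus = Corpus(documents=documents, name=name)
    corpus.validate()
    return corpus


def corpus_to_json(c: Corpus) -> dict:
    """Canonical JSON form: mentions sorted by offsets, relations by position."""
    docs = []
    for d in c.documents:
        sentences = []
        for s in d.sentences:
            order = sorted(
                range(len(s.mentions)),
                key=lambda i: (s.mentions[i].char_span.start, s.mentions[i].char_span.end,
                               s.mentions[i].etype.value, s.mentions[i].provenance.value),
            )
            remap = {old: new for new, old in enumerate(order)}
            sentences.append(
                {
                    "sid": s.sid,
                    "text": s.text,
                    "mentions": [
                        {
                            "etype": s.mentions[i].etype.value,
                            "start": s.mentions[i].char_span.start,
                            "end": s.mentions[i].char_span.end,
                            "norm_id": s.mentions[i].norm_id,
                            "provenance": s.mentions[i].provenance.value,
                        }
                        for i in order
                    ],
                    "_remap": remap,
                }
            )
        rels = sorted(
            (
                {
                    "sid": r.sid,
                    "drug_idx": next(sj for sj in sentences if sj["sid"] == r.sid)["_remap"][r.drug_idx],
                    "cond_idx": next(sj for sj in sentences if sj["sid"] == r.sid)["_remap"][r.cond_idx],
                }
                for r in d.gold_relations
            ),
            key=lambda r: (r["sid"], r["drug_idx"], r["cond_idx"]),
        )
        for sj in sentences:
            del sj["_remap"]
        docs.append({"doc_id": d.doc_id, "sentences": sentences, "relations": rels})
    return {"name": c.name, "documents": docs}


def write_corpus(c: Corpus, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(corpus_to_json(c), indent=2, ensure_ascii=False) + "\n", encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# Corpus statistics
# ---------------------------------------------------------------------------

def corpus_stats(c: Corpus) -> dict[str, int]:
    """Tallies matching the convention of corpus summary tables: drugs and
    conditions are counted as mention instances, not unique strings; TRUE and
    FALSE counts are taken from the labelled candidate dataset (after nested
    removal)."""
    from . import instance_builder  # local import: instance_builder depends on this module

    n_drugs = n_conds = n_cand_sentences = 0
    for d in c.documents:
        for s in d.sentences:
            drugs = len(s.mentions_of(EntityType.DRUG))
            conds = len(s.mentions_of(EntityType.CONDITION))
            n_drugs += drugs
            n_conds += conds
            if drugs and conds:
                n_cand_sentences += 1
    dataset = instance_builder.build_dataset(c)
    n_true = sum(1 for cand in dataset if cand.label is Label.TRUE)
    n_false = sum(1 for cand in dataset if cand.label is Label.FALSE)
    return {
        "documents": len(c.documents),
        "drugs": n_drugs,
        "conditions": n_conds,
        "sentences_with_candidates": n_cand_sentences,
        "true_relations": n_true,
        "false_relations": n_false,
    }


# ---------------------------------------------------------------------------
# SRE line format
# ---------------------------------------------------------------------------

_SRE_LABEL = {Label.TRUE: "1", Label.FALSE: "0"}
_SRE_LABEL_INV = {"1": Label.TRUE, "0": Label.FALSE}
_FIELD_SEP = "&&"


class AnnotationIncompleteError(ValueError):
    """Raised when tokens lack lemma/POS needed for the SRE encoding."""


def _sre_token(idx: int, tok: Token, etype: str, role: str) -> str:
    fields = (str(idx), tok.text, tok.lemma, tok.pos, etype, role)
    for f in fields:
        if _FIELD_SEP in f or "\t" in f or " " in f or "\n" in f:
            raise CorpusFormatError(f"token field {f!r} contains a reserved separator")
    return _FIELD_SEP.join(fields)


def write_sre(dataset: Sequence["instance_builder.RelationCandidate"], path: str | Path) -> None:
    """Write candidates as SRE lines: ``<label>\\t<id>\\t<token stream>``.

    Each token is ``index&&text&&lemma&&pos&&etype|O&&role`` (role A = candidate
    drug, T = candidate condition, O = other).  Candidates are ordered by
    (doc_id, sentence id, drug offset, condition offset).
    """
    ordered = sorted(
        dataset,
        key=lambda cd: (cd.doc_id, cd.sid, cd.drug.char_span.start, cd.condition.char_span.start),
    )
    lines = []
    for cand in ordered:
        sent = cand.sentence
        for tok in sent.tokens:
            if not tok.lemma or not tok.pos:
                raise AnnotationIncompleteError(
                    f"candidate {cand.instance_id!r}: token {tok.text!r} lacks lemma or POS"
                )
        etype_of: dict[int, str] = {}
        for m in sent.mentions:
            for i in range(m.token_span.start, m.token_span.end):
                etype_of.setdefault(i, m.etype.value)
        parts = []
        for i, tok in enumerate(sent.tokens):
            if cand.drug.token_span.start <= i < cand.drug.token_span.end:
                role = "A"
            elif cand.condition.token_span.start <= i < cand.condition.token_span.end:
                role = "T"
            else:
                role = "O"
            parts.append(_sre_token(i, tok, etype_of.get(i, "O"), role))
        label = _SRE_LABEL.get(cand.label)
        if label is None:
            raise CorpusFormatError(
                f"candidate {cand.instance_id!r} has label {cand.label.value}; "
                "only TRUE/FALSE can be serialized"
            )
        lines.append(f"{label}\t{cand.instance_id}\t{' '.join(parts)}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def read_sre(path: str | Path) -> list["instance_builder.RelationCandidate"]:
    """Inverse of :func:`write_sre` up to canonical ordering.

    Sentence text is reconstructed by joining token surface forms with single
    spaces; character offsets are recomputed accordingly.
    """
    from .instance_builder import RelationCandidate

    out: list[RelationCandidate] = []
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), start=1):
        if not raw.strip():
            continue
        parts = raw.split("\t")
        if len(parts) != 3:
            raise CorpusFormatError(f"line {lineno}: expected 3 tab-separated fields")
        label_s, instance_id, stream = parts
        if label_s not in _SRE_LABEL_INV:
            raise CorpusFormatError(f"line {lineno}: unknown label {label_s!r}")
        tokens: list[Token] = []
        etypes: list[str] = []
        roles: list[str] = []
        cursor = 0
        for tok_s in stream.split(" "):
            fields = tok_s.split(_FIELD_SEP)
            if len(fields) != 6:
                raise CorpusFormatError(
                    f"line {lineno}: token {tok_s!r} has {len(fields)} fields, expected 6"
                )
            _, text, lemma, pos, etype, role = fields
            span = Span(cursor, cursor + len(text))
            tokens.append(Token(text=text, lemma=lemma, pos=pos, ortho=ortho_class(text), span=span))
            etypes.append(etype)
            roles.append(role)
            cursor = span.end + 1
        text = " ".join(t.text for t in tokens)
        sent = Sentence(sid="", text=text, tokens=tokens)

        def runs_of(flag: Callable[[int], bool]) -> list[Span]:
            spans, start = [], None
            for i in range(len(tokens) + 1):
                active = i < len(tokens) and flag(i)
                if active and start is None:
                    start = i
                elif not active and start is not None:
                    spans.append(Span(start, i))
                    start = None
            return spans

        def mention(tok_span: Span, etype: EntityType) -> EntityMention:
            return EntityMention(
                etype=etype,
                token_span=tok_span,
                char_span=Span(tokens[tok_span.start].span.start, tokens[tok_span.end - 1].span.end),
                provenance=Provenance.MACHINE,
            )

        def candidate_span(role: str, other: str) -> Span:
            # A nested candidate entity interrupts the other entity's run
            # (e.g. a drug token inside a condition phrase), so runs of
            # ``role`` separated only by ``other``-role tokens are one entity.
            runs = runs_of(lambda i: roles[i] == role)
            if not runs:
                raise CorpusFormatError(
                    f"line {lineno}: no candidate tokens with role {role!r}"
                )
            lo, hi = runs[0].start, runs[-1].end
            if any(roles[i] not in (role, other) for i in range(lo, hi)):
                raise CorpusFormatError(
                    f"line {lineno}: candidate role {role!r} tokens are not contiguous"
                )
            return Span(lo, hi)

        drug = mention(candidate_span("A", "T"), EntityType.DRUG)
        cond = mention(candidate_span("T", "A"), EntityType.CONDITION)
        other = [
            mention(sp, EntityType(et))
            for et in ("DRUG", "CONDITION")
            for sp in runs_of(lambda i, et=et: roles[i] == "O" and etypes[i] == et)
        ]
        sent.mentions = [drug, cond, *other]
        doc_id, sid = instance_id, ""
        if ":" in instance_id:
            bits = instance_id.split(":")
            if len(bits) >= 3:
                doc_id, sid = bits[0], bits[1]
        sent.sid = sid
        out.append(
            RelationCandidate(
                doc_id=doc_id,
                sid=sid,
                sentence=sent,
                drug=drug,
                condition=cond,
                label=_SRE_LABEL_INV[label_s],
                instance_id=instance_id,
            )
        )
    return sorted(out, key=lambda cd: (cd.doc_id, cd.sid, cd.drug.char_span.start,
                                       cd.condition.char_span.start))
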