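"""Dictionary-based named entity recognition.

Tags drug and condition mentions from terminology tables (DrugBank-style and
MedDRA-style TSV lexicons), filling annotation gaps left by human annotators.
Matching is token-sequence based after case-folding, longest-match first,
left-to-right, and never overrides or overlaps an existing human annotation.
Machine mentions produced here are what turns unannotated drug–condition
co-occurrences into negative (FALSE) relation candidates downstream.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

from .corpus_model import (
    Corpus,
    EntityMention,
    EntityType,
    Provenance,
    Sentence,
    Span,
)

logger = logging.getLogger(__name__)

_WS_RE = re.compile(r"\s+")


def normalize_term(term: str) -> str:
    """Case-fold and collapse internal whitespace."""
    return _WS_RE.sub(" ", term.strip().casefold())


@dataclass
class Lexicon:
    """Surface term -> normalized identifier map for one entity type."""

    etype: EntityType
    entries: dict[str, str] = field(default_factory=dict)
    name: str = "lexicon"

    def __post_init__(self) -> None:
        for key in self.entries:
            if not key or key != normalize_term(key):
                raise ValueError(f"lexicon {self.name!r}: key {key!r} is not normalized")

    def __len__(self) -> int:
        return len(self.entries)


class LexiconFormatError(ValueError):
    pass


def load_lexicon(path: str | Path, etype: EntityType, name: str | None = None) -> Lexicon:
    """Load a two-column TSV (term, identifier) lexicon.

    Terms are case-folded; synonym rows may repeat an identifier.  A term that
    reappears with a conflicting identifier keeps its first mapping (a warning
    is logged).  '#'-prefixed lines are comments.
    """
    path = Path(path)
    entries: dict[str, str] = {}
    n_rows = 0
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        parts = raw.split("\t")
        if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
            raise LexiconFormatError(f"{path}:{lineno}: expected 'term<TAB>identifier'")
        term, ident = normalize_term(parts[0]), parts[1].strip()
        n_rows += 1
        if term in entries:
            if entries[term] != ident:
                logger.warning(
                    "%s:%d: term %r maps to %r, keeping first mapping %r",
                    path, lineno, term, ident, entries[term],
                )
            continue
        entries[term] = ident
    if n_rows == 0:
        raise LexiconFormatError(f"{path}: empty lexicon")
    return Lexicon(etype=etype, entries=entries, name=name or path.stem)


def _token_key(sentence: Sentence, start: int, end: int) -> str:
    """Normalized key of the token window [start, end) as it would appear in
    a whitespace-normalized term."""
    return normalize_term(
        sentence.text[sentence.tokens[start].span.start : sentence.tokens[end - 1].span.end]
    )


def match(s: Sentence, lex: Lexicon) -> list[EntityMention]:
    """Longest-match, left-to-right dictionary matching over token sequences.

    Case-insensitive; candidate windows overlapping any HUMAN mention (of
    either entity type) are discarded, as are windows overlapping an earlier
    (longer or more leftward) match.  Matches carry the lexicon identifier
    and provenance MACHINE.
    """
    if not s.tokens:
        return []
    max_len = 1
    for key in lex.entries:
        max_len = max(max_len, key.count(" ") + 1)
    human_spans = [m.char_span for m in s.mentions if m.provenance is Provenance.HUMAN]
    claimed: list[Span] = []
    out: list[EntityMention] = []
    i = 0
    n = len(s.tokens)
    while i < n:
        hit = None
        for j in range(min(n, i + max_len), i, -1):  # longest window first
            key = _token_key(s, i, j)
            ident = lex.entries.get(key)
            if ident is None:
                continue
            char_span = Span(s.tokens[i].span.start, s.tokens[j - 1].span.end)
            if any(char_span.overlaps(h) for h in human_spans):
                continue
            if any(char_span.overlaps(cs) for cs in claimed):
                continue
            hit = (j, char_span, ident)
            break
        if hit is None:
            i += 1
            continue
        j, char_span, ident = hit
        claimed.append(char_span)
        out.append(
            EntityMention(
                etype=lex.etype,
                token_span=Span(i, j),
                char_span=char_span,
                norm_id=ident,
                provenance=Provenance.MACHINE,
            )
        )
        i = j
    return out


def annotate_corpus(c: Corpus, drug_lex: Lexicon, cond_lex: Lexicon) -> Corpus:
    """Add MACHINE mentions for lexicon hits not already annotated.

    Human annotations are left untouched; the operation is idempotent because
    machine mentions from a previous run suppress re-matching of their spans.
    Drug matches are resolved before condition matches; a condition match
    never overlaps an accepted drug match.
    """
    if drug_lex.etype is not EntityType.DRUG:
        raise ValueError(f"drug lexicon has etype {drug_lex.etype.value}")
    if cond_lex.etype is not EntityType.CONDITION:
        raise ValueError(f"condition lexicon has etype {cond_lex.etype.value}")
    for d in c.documents:
        for s in d.sentences:
            existing = [m.char_span for m in s.mentions]
            added: list[EntityMention] = []
            for lex in (drug_lex, cond_lex):
                for m in match(s, lex):
                    if any(m.char_span.overlaps(sp) for sp in existing):
                        continue
                    added.append(m)
                    existing.append(m.char_span)
            s.mentions.extend(added)
    c.validate()
    return c
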