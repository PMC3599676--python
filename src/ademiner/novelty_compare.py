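"""Aggregation of predicted adverse event relations and comparison against a
side-effect reference table.

Predicted TRUE relations are aggregated into distinct normalized
(drug identifier, event identifier) pairs with their supporting evidence.
Pairs absent from a reference of known drug side effects (a SIDER-style
drug-label table) are candidate *novel* signals; a second reference (e.g. a
regulatory label-change list) can then be intersected to validate them.
Comparison is strictly in identifier space: candidates whose mentions lack a
normalized identifier are tallied and skipped, never string-matched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .corpus_model import Label
from .instance_builder import RelationCandidate

logger = logging.getLogger(__name__)

Pair = tuple[str, str]  # (drug_id, event_id)


@dataclass
class PairSupport:
    count: int = 0
    doc_ids: set[str] = field(default_factory=set)


@dataclass
class PairLedger:
    pairs: dict[Pair, PairSupport] = field(default_factory=dict)
    skipped_unnormalized: int = 0

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def n_drugs(self) -> int:
        return len({d for d, _ in self.pairs})

    @property
    def n_events(self) -> int:
        return len({e for _, e in self.pairs})


@dataclass
class ReferenceTable:
    pairs: set[Pair] = field(default_factory=set)
    source: str = "reference"

    def __len__(self) -> int:
        return len(self.pairs)


class ReferenceFormatError(ValueError):
    pass


def aggregate(preds: Iterable[RelationCandidate]) -> PairLedger:
    """Distinct-pair ledger over predicted (or gold) TRUE candidates.

    Candidates not labelled TRUE are ignored; TRUE candidates with a missing
    drug or condition identifier are counted in ``skipped_unnormalized`` and
    logged once at the end.
    """
    ledger = PairLedger()
    for cd in preds:
        if cd.label is not Label.TRUE:
            continue
        if not cd.drug.norm_id or not cd.condition.norm_id:
            ledger.skipped_unnormalized += 1
            continue
        sup = ledger.pairs.setdefault((cd.drug.norm_id, cd.condition.norm_id), PairSupport())
        sup.count += 1
        sup.doc_ids.add(cd.doc_id)
    if ledger.skipped_unnormalized:
        logger.warning(
            "aggregate: skipped %d TRUE predictions lacking normalized identifiers",
            ledger.skipped_unnormalized,
        )
    return ledger


def load_reference(path: str | Path, source: str | None = None) -> ReferenceTable:
    """Two-column TSV of (drug_id, event_id); duplicates collapse; '#' lines
    are comments; an empty file yields an empty table."""
    path = Path(path)
    pairs: set[Pair] = set()
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        parts = raw.split("\t")
        if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
            raise ReferenceFormatError(f"{path}:{lineno}: expected 'drug_id<TAB>event_id'")
        pairs.add((parts[0].strip(), parts[1].strip()))
    return ReferenceTable(pairs=pairs, source=source or path.stem)


def load_bundled_reference(name: str) -> ReferenceTable:
    """Load one of the reference tables shipped with the package
    (``mhra_2009_label_changes.tsv``, ``sider_like_reference_synthetic.tsv``)."""
    ref = resources.files("ademiner") / "data" / name
    with resources.as_file(ref) as path:
        return load_reference(path, source=name)


def novel_pairs(
    ledger: PairLedger, ref: ReferenceTable, min_support: int = 1
) -> list[tuple[str, str, int]]:
    """Ledger pairs absent from the reference with support >= min_support,
    sorted by support descending then lexicographically.  Returned as
    (drug_id, event_id, support_count) triples."""
    out = [
        (drug, event, sup.count)
        for (drug, event), sup in ledger.pairs.items()
        if (drug, event) not in ref.pairs and sup.count >= min_support
    ]
    out.sort(key=lambda t: (-t[2], t[0], t[1]))
    return out


def validate_against(
    novel: Sequence[tuple[str, str, int]], validation: ReferenceTable
) -> list[tuple[str, str, int]]:
    """Subset of novel pairs corroborated by a validation reference (e.g. a
    table of regulatory drug-label changes)."""
    return [t for t in novel if (t[0], t[1]) in validation.pairs]
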