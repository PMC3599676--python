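"""Corpus domain model, standoff JSON and SRE serialisation."""

from __future__ import annotations

import json

import pytest

from ademiner.corpus_model import (
    AnnotationIncompleteError,
    Corpus,
    CorpusFormatError,
    CorpusValidationError,
    EntityType,
    Label,
    Span,
    Token,
    corpus_stats,
    default_annotator,
    ortho_class,
    read_corpus,
    read_sre,
    write_corpus,
    write_sre,
)
from ademiner.instance_builder import build_dataset
from ademiner.synthetic_corpus import GeneratorConfig, generate

from conftest import make_sentence, one_sentence_corpus

DRUG, COND = EntityType.DRUG, EntityType.CONDITION


class TestAnnotator:
    def test_tokens_match_text_at_spans(self):
        text = "Treatment with lithium caused acute toxicity (3/4)."
        for tok in default_annotator(text):
            assert text[tok.span.start : tok.span.end] == tok.text

    def test_splits_punctuation(self):
        texts = [t.text for t in default_annotator("nausea, vomiting.")]
        assert texts == ["nausea", ",", "vomiting", "."]

    def test_deterministic(self):
        text = "Niacin maculopathy was seen."
        assert default_annotator(text) == default_annotator(text)

    @pytest.mark.parametrize(
        "word,expected",
        [
            ("lithium", "ALPHA_LOWER"),
            ("Niacin", "ALPHA_CAP"),
            ("mRNA", "ALPHA_MIXED"),
            ("42", "DIGIT"),
            ("5FU", "ALNUM"),
            (",", "PUNCT"),
        ],
    )
    def test_ortho_classes(self, word, expected):
        assert ortho_class(word) == expected

    def test_lemma_is_lowercase(self):
        for tok in default_annotator("Seizures Occurred After Therapy"):
            assert tok.lemma == tok.lemma.lower()


class TestStandoffJson:
    def _tiny_file(self, tmp_path):
        payload = {
            "name": "tiny",
            "documents": [
                {
                    "doc_id": "123",
                    "sentences": [
                        {
                            "sid": "s0",
                            "text": "lithium caused tremor .",
                            "mentions": [
                                {"etype": "DRUG", "start": 0, "end": 7,
                                 "norm_id": "D1", "provenance": "HUMAN"},
                                {"etype": "CONDITION", "start": 15, "end": 21,
                                 "norm_id": "C1", "provenance": "HUMAN"},
                            ],
                        }
                    ],
                    "relations": [{"sid": "s0", "drug_idx": 0, "cond_idx": 1}],
                }
            ],
        }
        path = tmp_path / "tiny.json"
        path.write_text(json.dumps(payload))
        return path

    def test_exact_counts(self, tmp_path):
        corpus = read_corpus(self._tiny_file(tmp_path))
        assert len(corpus.documents) == 1
        doc = corpus.documents[0]
        assert len(doc.sentences) == 1
        sent = doc.sentences[0]
        assert len(sent.mentions_of(DRUG)) == 1
        assert len(sent.mentions_of(COND)) == 1
        assert len(doc.gold_relations) == 1

    def test_round_trip_byte_identical(self, tmp_path):
        corpus = read_corpus(self._tiny_file(tmp_path))
        out1, out2 = tmp_path / "a.json", tmp_path / "b.json"
        write_corpus(corpus, out1)
        write_corpus(read_corpus(out1), out2)
        assert out1.read_bytes() == out2.read_bytes()

    def test_offset_beyond_text_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps({
            "documents": [{
                "doc_id": "1",
                "sentences": [{"sid": "s0", "text": "short",
                               "mentions": [{"etype": "DRUG", "start": 0, "end": 99}]}],
                "relations": [],
            }]
        }))
        with pytest.raises(CorpusValidationError):
            read_corpus(path)

    def test_malformed_record_names_doc(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps({
            "documents": [{
                "doc_id": "77",
                "sentences": [{"sid": "s0", "text": "abc def",
                               "mentions": [{"etype": "NOPE", "start": 0, "end": 3}]}],
            }]
        }))
        with pytest.raises(CorpusFormatError, match="77"):
            read_corpus(path)

    def test_not_json_is_format_error(self, tmp_path):
        path = tmp_path / "garbage.json"
        path.write_text("{{{")
        with pytest.raises(CorpusFormatError):
            read_corpus(path)

    def test_synthetic_corpus_round_trips(self, tmp_path, small_synth):
        corpus, _ = small_synth
        out1, out2 = tmp_path / "a.json", tmp_path / "b.json"
        write_corpus(corpus, out1)
        write_corpus(read_corpus(out1), out2)
        assert out1.read_bytes() == out2.read_bytes()


class TestCorpusStats:
    def test_empty_corpus_all_zero(self):
        assert all(v == 0 for v in corpus_stats(Corpus(documents=[])).values())

    def test_one_drug_two_conditions_one_gold(self):
        sent = make_sentence(
            "morzanib caused kelvurosis and betfexemia .",
            [(0, 8, DRUG), (16, 26, COND), (31, 41, COND)],
        )
        stats = corpus_stats(one_sentence_corpus(sent, relations=[(0, 1)]))
        assert stats["drugs"] == 1
        assert stats["conditions"] == 2
        assert stats["true_relations"] == 1
        assert stats["false_relations"] == 1  # 1x2 pairs minus 1 gold

    def test_counts_match_generator_ledger(self, small_synth):
        corpus, ledger = small_synth
        stats = corpus_stats(corpus)
        assert stats["documents"] == 50
        assert stats["true_relations"] == ledger.n_true
        assert stats["false_relations"] == ledger.n_false + ledger.n_nested

    def test_additive_over_disjoint_union(self, small_synth):
        corpus, _ = small_synth
        half = len(corpus.documents) // 2
        left = Corpus(documents=corpus.documents[:half], name="left")
        right = Corpus(documents=corpus.documents[half:], name="right")
        total = corpus_stats(corpus)
        sl, sr = corpus_stats(left), corpus_stats(right)
        assert all(total[k] == sl[k] + sr[k] for k in total)


class TestSre:
    def test_label_encoding(self, tmp_path, small_synth):
        corpus, _ = small_synth
        dataset = build_dataset(corpus)
        path = tmp_path / "data.sre"
        write_sre(dataset, path)
        lines = path.read_text().splitlines()
        assert len(lines) == len(dataset)
        by_id = {cd.instance_id: cd for cd in dataset}
        for line in lines:
            label, iid, _ = line.split("\t")
            assert label == ("1" if by_id[iid].label is Label.TRUE else "0")

    def test_round_trip_labels_ids_tokens(self, tmp_path, small_synth):
        corpus, _ = small_synth
        dataset = sorted(build_dataset(corpus), key=lambda cd: cd.instance_id)
        path = tmp_path / "data.sre"
        write_sre(dataset, path)
        back = sorted(read_sre(path), key=lambda cd: cd.instance_id)
        assert [cd.instance_id for cd in back] == [cd.instance_id for cd in dataset]
        assert [cd.label for cd in back] == [cd.label for cd in dataset]
        for a, b in zip(dataset, back):
            assert [(t.text, t.lemma, t.pos) for t in a.sentence.tokens] == [
                (t.text, t.lemma, t.pos) for t in b.sentence.tokens
            ]

    def test_write_read_write_is_stable(self, tmp_path, small_synth):
        corpus, _ = small_synth
        dataset = build_dataset(corpus)
        p1, p2 = tmp_path / "a.sre", tmp_path / "b.sre"
        write_sre(dataset, p1)
        write_sre(read_sre(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_bad_token_field_count(self, tmp_path):
        path = tmp_path / "bad.sre"
        path.write_text("1\tid1\t0&&drug&&drug&&NOUN&&DRUG\n")  # 5 fields
        with pytest.raises(CorpusFormatError, match="line 1"):
            read_sre(path)

    def test_missing_annotation_rejected(self, tmp_path):
        cand = _candidate_without_pos()
        with pytest.raises(AnnotationIncompleteError):
            write_sre([cand], tmp_path / "x.sre")


def _candidate_without_pos():
    from ademiner.instance_builder import RelationCandidate

    sent = make_sentence("morzanib caused kelvurosis .", [(0, 8, DRUG), (16, 26, COND)])
    stripped = [Token(text=t.text, lemma=t.lemma, pos="", ortho=t.ortho, span=t.span)
                for t in sent.tokens]
    sent.tokens = stripped
    return RelationCandidate(doc_id="d", sid="s0", sentence=sent,
                             drug=sent.mentions[0], condition=sent.mentions[1],
                             label=Label.TRUE)
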