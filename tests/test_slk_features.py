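"""Shallow linguistic kernel: segment features, normalization, algebra."""

from __future__ import annotations

import math
import random

import numpy as np
import pytest

from ademiner.corpus_model import EntityType
from ademiner.instance_builder import build_dataset
from ademiner.slk_features import (
    KernelParams,
    SUBKERNELS,
    feature_map,
    featurize,
    global_context,
    kernel,
    local_context,
)
from ademiner.synthetic_corpus import GeneratorConfig, generate

from conftest import make_candidate

P = KernelParams()  # n_max=3, window=2, blind entities


def brute_force_ngram_counts(lemmas: list[str], n_max: int) -> dict[str, int]:
    """Independent oracle: enumerate every contiguous n-gram explicitly."""
    counts: dict[str, int] = {}
    for n in range(1, n_max + 1):
        for i in range(len(lemmas)):
            if i + n <= len(lemmas):
                key = "_".join(lemmas[i : i + n])
                counts[key] = counts.get(key, 0) + 1
    return counts


def dense_kernel_oracle(a, b, p: KernelParams) -> float:
    """Independent dense-vector computation of the kernel: per sub-kernel,
    materialize count vectors over the union vocabulary and use numpy."""
    va, vb = featurize(a, p), featurize(b, p)
    total = 0.0
    for sub in SUBKERNELS:
        prefixes = ("LC_LEFT:", "LC_RIGHT:") if sub == "LC" else (sub + ":",)
        ea = {k: v for k, v in va.entries.items() if k.startswith(prefixes)}
        eb = {k: v for k, v in vb.entries.items() if k.startswith(prefixes)}
        vocab = sorted(set(ea) | set(eb))
        if not vocab:
            continue
        xa = np.array([ea.get(k, 0.0) for k in vocab])
        xb = np.array([eb.get(k, 0.0) for k in vocab])
        na, nb = np.linalg.norm(xa), np.linalg.norm(xb)
        if na == 0 or nb == 0:
            continue
        total += float(xa @ xb) / (na * nb)
    return total


@pytest.fixture(scope="module")
def random_candidates():
    cfg = GeneratorConfig(n_docs=30, unannotated_rate=0.0, seed=17)
    corpus, _ = generate(cfg)
    dataset = build_dataset(corpus)
    rng = random.Random(17)
    return rng.sample(dataset, 50)


class TestGlobalContext:
    def test_adjacent_entities_empty_between(self):
        cand = make_candidate("morzanib betfexemia noted .", (0, 8), (9, 19))
        vec = global_context(cand, P)
        assert vec.restrict("B") == {}

    def test_single_between_token(self):
        cand = make_candidate("morzanib induced betfexemia", (0, 8), (17, 27))
        vec = global_context(cand, KernelParams(n_max=1))
        assert vec.restrict("B") == {"B:induced": 1}

    def test_between_ngram_count_five_tokens(self):
        # 5 tokens between the entities, n_max=3: 5 + 4 + 3 = 12 n-grams
        cand = make_candidate(
            "morzanib was linked to the subsequent betfexemia", (0, 8), (38, 48)
        )
        vec = global_context(cand, P)
        assert sum(vec.restrict("B").values()) == 12

    def test_between_counts_match_brute_force(self):
        rng = random.Random(3)
        words = ["was", "linked", "to", "a", "new", "case", "of", "again", "again"]
        for _ in range(100):
            middle = [rng.choice(words) for _ in range(rng.randint(0, 6))]
            text = " ".join(["morzanib", *middle, "betfexemia"])
            cond_start = len(text) - len("betfexemia")
            cand = make_candidate(text, (0, 8), (cond_start, len(text)))
            n_max = rng.randint(1, 4)
            vec = global_context(cand, KernelParams(n_max=n_max))
            got = {k.split(":", 1)[1]: int(v) for k, v in vec.restrict("B").items()}
            assert got == brute_force_ngram_counts(middle, n_max)

    def test_blinding_replaces_entity_lemmas(self):
        cand = make_candidate("morzanib induced betfexemia", (0, 8), (17, 27))
        vec = global_context(cand, P)
        assert not any("morzanib" in k or "betfexemia" in k for k in vec.entries)
        assert any("DRUG_CAND" in k for k in vec.restrict("FB"))
        unblinded = global_context(cand, KernelParams(blind_entities=False))
        assert any("morzanib" in k for k in unblinded.entries)

    def test_entity_order_follows_sentence_not_roles(self):
        # condition appears before the drug: FB must start from the condition side
        cand = make_candidate("betfexemia followed morzanib therapy", (20, 28), (0, 10))
        vec = global_context(cand, KernelParams(n_max=1))
        assert "FB:COND_CAND" in vec.entries
        assert "BA:therapy" in vec.entries


class TestLocalContext:
    def test_window_zero_empty(self):
        cand = make_candidate("morzanib induced betfexemia", (0, 8), (17, 27))
        vec = local_context(cand, KernelParams(window=0))
        assert len(vec) == 0

    def test_sentence_start_only_right_side(self):
        cand = make_candidate("morzanib induced betfexemia", (0, 8), (17, 27))
        vec = local_context(cand, KernelParams(window=2))
        left_of_drug = [k for k in vec.restrict("LC_LEFT") if k.split(":")[1].startswith("-")]
        assert left_of_drug == []

    def test_mid_sentence_sixteen_keys_per_entity(self):
        # window=2 around a mid-sentence entity: 4 positions x 4 attributes
        cand = make_candidate(
            "the drug morzanib induced a betfexemia episode today", (9, 17), (28, 38)
        )
        vec = local_context(cand, KernelParams(window=2))
        assert len(vec.restrict("LC_LEFT")) == 16
        assert len(vec.restrict("LC_RIGHT")) == 16

    def test_positions_enumerated_exactly(self):
        cand = make_candidate(
            "the drug morzanib induced a betfexemia episode today", (9, 17), (28, 38)
        )
        vec = local_context(cand, KernelParams(window=1))
        rels = {k.split(":")[1] for k in vec.restrict("LC_LEFT")}
        assert rels == {"-1", "1"}


class TestKernelAlgebra:
    def test_self_kernel_counts_nonempty_subkernels(self):
        cand = make_candidate("morzanib induced betfexemia", (0, 8), (17, 27))
        # fore empty, between non-empty, after empty: FB, B, BA, LC all non-empty
        assert kernel(cand, cand, P) == pytest.approx(4.0, abs=1e-12)

    def test_self_kernel_missing_between(self):
        cand = make_candidate("morzanib betfexemia", (0, 8), (9, 19))
        # between empty and nothing else in the sentence: B contributes 0,
        # FB/BA still see the placeholders, LC sees the other entity
        assert kernel(cand, cand, P) == pytest.approx(3.0, abs=1e-12)

    def test_disjoint_vocabulary_zero(self):
        a = make_candidate("morzanib induced betfexemia", (0, 8), (17, 27))
        b = make_candidate("kelwexib prevented dalsabitis", (0, 8), (19, 29))
        # blinding shares the placeholders and the local-context window shares
        # POS/ortho attributes; disable both for true vocabulary disjointness
        p = KernelParams(blind_entities=False, window=0)
        assert kernel(a, b, p) == 0.0

    def test_hand_computed_toy_value(self):
        # n_max=1, window=0: only unigram global contexts contribute.
        a = make_candidate("morzanib induced betfexemia", (0, 8), (17, 27))
        b = make_candidate("kelwexib induced dalsabitis", (0, 8), (17, 27))
        p = KernelParams(n_max=1, window=0)
        # per namespace, blinded unigrams are identical between a and b:
        # FB = {DRUG_CAND, induced}, B = {induced}, BA = {induced, COND_CAND}
        assert kernel(a, b, p) == pytest.approx(3.0, abs=1e-12)

    def test_symmetry(self, random_candidates):
        rng = random.Random(1)
        for _ in range(30):
            a, b = rng.sample(random_candidates, 2)
            assert kernel(a, b, P) == kernel(b, a, P)

    def test_matches_dense_oracle(self, random_candidates):
        rng = random.Random(2)
        for _ in range(30):
            a, b = rng.sample(random_candidates, 2)
            assert kernel(a, b, P) == pytest.approx(dense_kernel_oracle(a, b, P), abs=1e-12)

    def test_bounds(self, random_candidates):
        rng = random.Random(4)
        for _ in range(50):
            a, b = rng.sample(random_candidates, 2)
            assert 0.0 <= kernel(a, b, P) <= 4.0 + 1e-12


class TestFeatureMap:
    def test_norm_squared_equals_self_kernel(self, random_candidates):
        for cand in random_candidates[:20]:
            fm = feature_map(cand, P)
            norm_sq = sum(v * v for v in fm.entries.values())
            assert norm_sq == pytest.approx(kernel(cand, cand, P), abs=1e-10)

    def test_dot_products_equal_kernel(self, random_candidates):
        maps = [feature_map(cd, P) for cd in random_candidates]
        rng = random.Random(5)
        for _ in range(100):
            i, j = rng.randrange(len(maps)), rng.randrange(len(maps))
            dot = sum(v * maps[j].entries.get(k, 0.0) for k, v in maps[i].entries.items())
            assert abs(dot - kernel(random_candidates[i], random_candidates[j], P)) < 1e-10

    def test_degenerate_nested_candidate_featurizable(self):
        # overlapping spans (drug inside condition): between collapses to empty
        cand = make_candidate("Acute morzanib toxicity required admission .", (6, 14), (0, 23))
        fm = feature_map(cand, P)
        assert fm.restrict("B") == {}
        assert len(fm.entries) > 0
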