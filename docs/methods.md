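# Methods

## Problem and overall design

`ademiner` extracts *potential adverse drug event* (ADE) relations from the
sentences of medical case reports.  The unit of classification is a
sentence-level candidate: an ordered pair (drug mention, condition mention)
co-occurring in one sentence, to be labelled TRUE (the sentence asserts the
condition as a potential adverse effect of the drug) or FALSE (mere
co-mention).  The pipeline is:

1. **Dictionary NER** (`lexicon_ner`) tags drugs and conditions from
   DrugBank-style and MedDRA-style terminology tables, filling the gaps left
   by human annotators.  Gold corpora of this kind are sparsely annotated —
   only entities participating in a true ADE relation are hand-marked — so
   machine annotation is what makes negative training instances possible.
2. **Instance construction** (`instance_builder`) enumerates every
   drug × condition pair per sentence, labels pairs matching a gold relation
   TRUE and all others FALSE, after removing *nested* gold relations whose
   drug and condition spans overlap (e.g. a drug name embedded in an
   intoxication phrase); those are not usable as sentence-level instances.
3. **Classification** (`slk_features`, `relation_classifier`) scores each
   candidate with a linear SVM over the explicit feature map of a shallow
   linguistic kernel.
4. **Evaluation** (`evaluation`) reports precision/recall/F over the TRUE
   class, by document-level k-fold cross-validation and held-out testing,
   plus a training-set-size (learning-curve) experiment.
5. **Novelty comparison** (`novelty_compare`) aggregates predicted TRUE
   relations into distinct normalized (drug id, event id) pairs and reports
   those absent from a drug-label side-effect reference — candidate signals
   for pharmacovigilance review.

## The shallow linguistic kernel

The similarity of two candidates is a sum of cosine-normalized sub-kernels

    K(a, b) = Σ_s K_s(a, b) / sqrt(K_s(a, a) · K_s(b, b)),   s ∈ {FB, B, BA, LC}

with each K_s a dot product of sparse count vectors, and a sub-kernel's term
defined as 0 when either self-similarity is 0.  Consequently
0 ≤ K(a, b) ≤ 4 and K(a, a) equals the number of non-empty sub-kernels.

**Global contexts (FB, B, BA).**  Each candidate entity is collapsed to a
single placeholder position (`DRUG_CAND` / `COND_CAND` when entity blinding
is on; its own lemma sequence otherwise).  With *fore* = positions before
the first entity, *between* = positions strictly between the entities and
*after* = positions after the second entity, the segments are

* FB = fore + [first entity] + between,
* B  = between,
* BA = between + [second entity] + after,

and each segment contributes its bag of contiguous lemma n-grams
(1 ≤ n ≤ `n_max`), counted with multiplicity.  Including the placeholder at
the segment boundary lets patterns such as "DRUG_CAND induced" participate;
the B segment deliberately excludes the entities, so adjacent entities give
an empty B sub-kernel.  For the degenerate pairs left behind by nested
removal (overlapping spans), the two placeholders are laid out adjacently
over the union span and B is empty.

**Local contexts (LC).**  For each candidate entity, every position at
relative offset r ∈ [−window, +window], r ≠ 0, of the collapsed sequence
contributes one feature per attribute in {surface form, lemma, POS tag,
orthographic class}, keyed by (side, r, attribute, value); the side namespace
is `LC_LEFT` for the entity occurring first in the sentence and `LC_RIGHT`
for the second.  Both sides are concatenated *before* normalization, forming
one LC sub-kernel.  Non-candidate entity mentions keep their tokens, but
their entity type is exposed through the orthographic attribute
(`ENT_DRUG` / `ENT_CONDITION`), so the classifier can see that a neighbouring
token is an entity without memorizing its name.

**Explicit feature map.**  `feature_map` scales each sub-kernel's block of
raw counts by 1/sqrt(K_s(x, x)), so dot products of maps equal kernel values
exactly (in exact arithmetic; the test suite bounds the float discrepancy at
1e−10).  Training a linear SVM on this map is therefore equivalent to the
kernel machine while scaling linearly in the number of candidates — the
property that makes literature-scale prediction practical.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `n_max` | 3 | longest global-context n-gram (tokens) |
| `window` | 2 | local-context half-width (token positions) |
| `blind_entities` | true | replace candidate entities by type placeholders |
| `C` | 1.0 | SVM regularization; no class reweighting (the TRUE:FALSE ratio is near-balanced in corpora of this design) |

Defaults follow common practice for this kernel family; all are exposed in
the API and the CLI.  Entity blinding is on by default because the goal is
to learn *contextual* evidence ("induced", "developed ... after") rather
than drug-specific priors.

## Numerical and procedural choices

* Character spans are 0-based and half-open, relative to sentence text,
  stated once and validated everywhere.
* The bundled annotator (tokenizer, coarse POS tagger, lemmatizer) is a
  small deterministic rule system: regex tokenization on word/punctuation
  boundaries, closed-class word lists plus suffix heuristics for POS, and
  lower-casing with plural stripping for lemmas.  The annotator is a
  pluggable callable; any richer tagger with the same signature can stand
  in.  Determinism is a requirement, not an optimization: corpus files and
  SRE files must be byte-reproducible.
* Nested gold relations are detected by non-empty character-span
  intersection of the two members — word containment generalized to any
  overlap.  Mentions are kept; only the relation is dropped, and the pair
  survives as an (unlearnable) FALSE candidate, preserving the exact
  |drugs| × |conditions| candidate arithmetic.
* Dictionary matching is token-sequence based after case-folding and
  whitespace normalization, longest-match first, left to right; a machine
  match never overlaps a human annotation or an earlier machine match.
  An exhaustive all-window matcher serves as the test oracle.
* Training canonicalizes the dataset by instance id before fitting, making
  the model invariant to input shuffling; the SVM seed is stored with the
  model.  A margin of exactly 0 predicts FALSE — the conservative choice
  for a precision-oriented safety application.
* Kernel dot products sum in sorted key order so that K(a, b) = K(b, a)
  holds bit-exactly.
* Cross-validation folds partition *documents* (round-robin over a seeded
  shuffle), never instances, so near-duplicate sentences from one case
  report cannot leak between train and test.  The headline CV number is
  micro-averaged from confusion counts summed over folds; the learning
  curve reports the mean and sample SD of per-fold scores, which is what
  published per-size SD columns reflect.
* The learning curve samples documents without replacement per size with a
  seed derived deterministically from (seed, size, repeat); sizes exceeding
  the corpus are skipped with a warning.

## The synthetic corpus generator

`synthetic_corpus.generate` emulates the statistical shape of an extended
ADE corpus rather than its language.  Sentences are drawn from *trigger*
templates, whose causal cue sits in the between-segment (so the deciding
signal is within `n_max` of the B sub-kernel by construction), and
*distractor* templates that co-mention entities without a cue.  Drug and
condition surfaces come from synthetic vocabularies with stable fake
DrugBank/MedDRA-style identifiers.  Defaults (100 drugs, 120 conditions,
3 sentences per document, 55% trigger sentences, 2% nested relations, 30%
of non-gold mentions left unannotated for NER to recover, label noise 0)
mirror the corpus-level ratios of the emulated setting: roughly 55:45
TRUE:FALSE instances, ~1.8% nested gold relations, and about a third of
entity mentions contributed by machine annotation.

Every planted pair, mention, identifier and noise flip is recorded in a
generation ledger, which is the single source of expected values for the
derived tests: no test asserts a count that the ledger does not entail.

What the generator does **not** model — and hence what passing tests do not
show about real text: lexical and syntactic diversity, coordination and
long-range dependencies, abbreviations and misspellings, frequency
annotations like "(3/4)", discontinuous or ambiguous mentions, and
terminology gaps between the lexicon and the text.  Published F ≈ 0.87 on a
real extended ADE corpus is *not* reproducible from this package alone; the
synthetic analogue at 200 clean documents instead checks that the pipeline
recovers a recoverable signal essentially perfectly (F ≥ 0.95), and the
noisy 2,000-document run checks the qualitative learning-curve shape
(rising mean, shrinking fold SD, ~1% SD at 2,000 documents).

## Problem sizes used by the shipped experiments

The test suite and `scripts/acceptance.py` run at fixture scale, chosen so a
single CPU covers them comfortably: 200 clean documents (~780 candidates)
for cross-validation and held-out testing, 2,000 noisy documents (~7,800
candidates) for the learning curve, 1,000 random sentences for the matcher
oracle, and 50 random candidates for the kernel-algebra checks.

## Known limitations

* The bundled POS tagger and lemmatizer are deliberately crude; with real
  text a proper tagger should be plugged into the annotator contract.
* Dictionary NER does no inflection handling, acronym resolution or fuzzy
  matching; recall on real text is bounded by lexicon coverage.
* Only intra-sentence relations are considered; inter-sentence ADE
  assertions are out of scope.
* The SRE line format does not carry character offsets or normalized ids;
  round-tripping through it preserves labels, instance ids and token
  attributes, not exact character geometry.
* No probability calibration: scores are SVM margins.
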