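# distantadr

Distant-supervision extraction of drug–effect relations — adverse drug
reactions (ADRs) and indications — from informal Spanish health-forum
messages.

## The problem

Patients describe drug experiences on health forums in lay, noisy Spanish
("me dio mucho mareo con el Sintrom"), long before those experiences show
up in spontaneous-reporting systems. Mining such posts for (drug, effect)
relations could surface unknown ADRs early, but hand-annotated training
corpora for Spanish social media barely exist. Distant supervision
side-steps annotation: if a drug and an effect co-occur in a message, the
pair *might* express a relation, and a knowledge base of known
drug–effect pairs supplies the (noisy) label. The package is aimed at
text-mining and pharmacovigilance researchers who want a transparent,
fully reproducible implementation of that recipe.

## The method

1. **Dictionary NER** — leftmost-longest, case/accent-insensitive
   gazetteer matching of drug and effect terms.
2. **Candidate generation** — every (drug, effect) mention pair within a
   250-token window in one message becomes a relation instance.
3. **Distant labeling** — an instance is POSITIVE iff its normalized
   (drug, effect) pair is in the knowledge base.
4. **Classification** — a soft-margin SVM over the precomputed Gram
   matrix of the **Shallow Linguistic (SL) kernel**,

   K_SL(x, y) = w_g · Σ_{C ∈ {FB, B, BA}} K̂_C(x, y) + w_l · (K̂_left(x, y) + K̂_right(x, y)),

   where each global term K_C is an n-gram kernel (n ≤ 3) over the
   Fore-Between, Between, and Between-After token contexts (stop-words
   and punctuation retained; candidate entities replaced by the
   placeholders CAND_DRUG / CAND_EFFECT), each local term counts shared
   {token, lemma, PoS, stem} features in a ±2 window around an entity,
   and K̂ denotes cosine normalization K̂(x,y) = K(x,y)/√(K(x,x)K(y,y)).
5. **Evaluation** — messages split 75/25; instance-level TP/FP/FN with
   precision, recall and F1, plus corpus profiling and BRAT-standoff gold
   evaluation.

Because the real forum corpus, gold corpus and drug–effect database are
not redistributable, the package ships a seeded synthetic-corpus
generator (`distantadr.synthetic`) that emulates them — pseudo-Spanish
messages with exact gold offsets, a matching KB with controllable
incompleteness, and seeded misspelling noise — so every stage is testable
end to end.

## Worked example

```bash
python examples/04_end_to_end.py
```

generates an 800-message synthetic corpus (complete KB, no spelling
noise), runs the full pipeline and prints:

```
TP=24 FP=0 FN=0
P=1.00 R=1.00 F1=1.00
```

i.e. on held-out messages every distantly-labeled positive pair was
recovered and nothing spurious was predicted — with a complete KB and
clean text the SL-kernel classifier separates cue-phrase contexts
perfectly. The interesting failure mode is KB incompleteness:

```bash
python examples/05_kb_incompleteness.py
```

```
keep_fraction  labeling_recall
         1.00  1.000
         0.75  0.789
         0.50  0.549
         0.25  0.268
```

Distant-label recall against gold falls roughly in proportion to the
relations removed from the KB — the central caveat of the paradigm.

The other examples demonstrate entity matching (`01`), distant labeling
(`02`) and the kernel itself (`03`); each prints the numbers it computes
and a one-line interpretation.

## Command line

```bash
distantadr simulate --seed 42 --n-messages 400 --out corpus/
distantadr run --config config.yaml --seed 42
```

Subcommands `ner`, `candidates`, `label`, `train`, `predict`, `evaluate`
and `gold` expose the individual stages over JSONL/TSV artifacts.

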