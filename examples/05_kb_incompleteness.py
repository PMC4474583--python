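"""How knowledge-base incompleteness erodes distant-supervision recall.

Distant labels are POSITIVE only when the pair is in the KB, so every
discarded relation silently flips true positives to negative training
labels. This sweep measures distant-label recall against synthetic gold
while keeping 100% / 75% / 50% / 25% of the KB's relations.
"""

import distantadr as d
from distantadr.candidates import POSITIVE, build_instances, distant_label
from distantadr.kb import subsample_kb
from distantadr.synthetic import GeneratorConfig, generate_corpus

corpus = generate_corpus(GeneratorConfig(n_messages=600, both_entity_rate=0.4,
                                         drug_only_rate=0.1, effect_only_rate=0.2,
                                         neither_rate=0.3, misspelling_rate=0.0, seed=8))
msgs = [d.analyze_message(m) for m in corpus.messages]
candidates = {
    m.id: build_instances(m, d.match_entities(m, corpus.gazetteer)) for m in msgs
}

print("keep_fraction  labeling_recall")
for keep in (1.0, 0.75, 0.5, 0.25):
    kb = subsample_kb(corpus.kb, keep, seed=8)
    tp = fn = 0
    for m in msgs:
        for inst in candidates[m.id]:
            truly = (inst.drug.canonical_id, inst.effect.canonical_id) in corpus.truth_pairs
            if truly:
                if distant_label(inst, kb).label == POSITIVE:
                    tp += 1
                else:
                    fn += 1
    print(f"{keep:13.2f}  {tp / (tp + fn):.3f}")

# Recall falls roughly in proportion to the discarded relations: the
# distant-supervision paradigm is only as complete as its knowledge base.
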