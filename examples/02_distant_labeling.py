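"""Distant supervision on a synthetic corpus.

Generates a seeded forum-like corpus with a matching knowledge base,
extracts windowed drug-effect candidates and labels them by KB lookup.
With the complete KB and no spelling noise, distant labels coincide with
the generator's gold relations exactly.
"""

import distantadr as d
from distantadr.candidates import POSITIVE, build_instances, distant_label
from distantadr.synthetic import GeneratorConfig, generate_corpus

corpus = generate_corpus(GeneratorConfig(n_messages=300, misspelling_rate=0.0, seed=4))

labeled = []
for message in corpus.messages:
    analyzed = d.analyze_message(message)
    mentions = d.match_entities(analyzed, corpus.gazetteer)
    for inst in build_instances(analyzed, mentions):
        labeled.append(distant_label(inst, corpus.kb))

n_pos = sum(1 for i in labeled if i.label == POSITIVE)
agreement = sum(
    1
    for i in labeled
    if (i.label == POSITIVE) == ((i.drug.canonical_id, i.effect.canonical_id) in corpus.truth_pairs)
)
print(f"messages:            {len(corpus.messages)}")
print(f"candidate instances: {len(labeled)}")
print(f"distant positives:   {n_pos}")
print(f"label/gold agreement: {agreement}/{len(labeled)}")

# Agreement equals the instance count: with a complete KB the distant
# label is the gold label. Real KBs are incomplete, which is this
# paradigm's main source of label noise.
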