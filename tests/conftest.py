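import pytest

import distantadr as d
from distantadr.candidates import build_instances, distant_label
from distantadr.synthetic import GeneratorConfig, generate_corpus


def corpus_instances(corpus, label=True):
    """Run NER + candidate extraction (+ distant labeling) over a corpus."""
    msgs = [d.analyze_message(m) for m in corpus.messages]
    mentions = {m.id: d.match_entities(m, corpus.gazetteer) for m in msgs}
    instances = []
    for m in msgs:
        insts = build_instances(m, mentions[m.id])
        if label:
            insts = [distant_label(i, corpus.kb) for i in insts]
        instances.extend(insts)
    return msgs, mentions, instances


def gold_label(instance, corpus):
    """POSITIVE iff the candidate's pair is in the generator's truth table."""
    pair = (instance.drug.canonical_id, instance.effect.canonical_id)
    return "POSITIVE" if pair in corpus.truth_pairs else "NEGATIVE"


@pytest.fixture(scope="session")
def clean_corpus():
    """A noise-free corpus with complete ground truth."""
    return generate_corpus(GeneratorConfig(n_messages=200, misspelling_rate=0.0, seed=11))


@pytest.fixture(scope="session")
def clean_instances(clean_corpus):
    _, _, instances = corpus_instances(clean_corpus)
    return instances


@pytest.fixture(scope="session")
def dense_corpus():
    """A corpus rich in drug+effect messages, for classifier tests."""
    cfg = GeneratorConfig(
        n_messages=1100,
        both_entity_rate=0.5,
        drug_only_rate=0.05,
        effect_only_rate=0.15,
        neither_rate=0.30,
        misspelling_rate=0.0,
        seed=7,
    )
    return generate_corpus(cfg)


@pytest.fixture(scope="session")
def dense_instances(dense_corpus):
    _, _, instances = corpus_instances(dense_corpus)
    return instances


def toy_instance(words, drug_span, effect_span, msg_id="t0"):
    """Build one fully featurized instance from a word list.

    ``drug_span`` / ``effect_span`` are (start, end) token index pairs.
    """
    from distantadr.candidates import extract_contexts, RelationInstance
    from distantadr.text import EntityMention, Message, analyze_message

    text = " ".join(words)
    message = analyze_message(Message(id=msg_id, text=text))
    tokens = message.tokens

    def mention(span, etype, cid):
        s, e = span
        return EntityMention(
            message_id=msg_id,
            entity_type=etype,
            token_start=s,
            token_end=e,
            char_start=tokens[s].char_start,
            char_end=tokens[e - 1].char_end,
            canonical_id=cid,
            surface=text[tokens[s].char_start : tokens[e - 1].char_end],
        )

    drug = mention(drug_span, "DRUG", "D0")
    effect = mention(effect_span, "EFFECT", "E0")
    inst = RelationInstance(id=f"{msg_id}:i", message_id=msg_id, drug=drug, effect=effect)
    return extract_contexts(message, inst)
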