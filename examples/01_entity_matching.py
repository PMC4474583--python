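"""Dictionary-based entity recognition over an informal Spanish message.

Builds a tiny drug/effect gazetteer and matches it against a forum-style
sentence, showing longest-match behaviour and accent/case insensitivity.
"""

import distantadr as d
from distantadr.text import LexiconEntry, Message

gazetteer = d.build_gazetteer(
    [
        LexiconEntry("Sintrom", "DRUG", "D001"),
        LexiconEntry("dolor de cabeza", "EFFECT", "E001"),
        LexiconEntry("dolor", "EFFECT", "E002"),
        LexiconEntry("depresión", "EFFECT", "E003"),
    ]
)

message = d.analyze_message(
    Message(id="demo", text="tomo SINTROM y ahora tengo dolor de cabeza y algo de depresion")
)

for m in d.match_entities(message, gazetteer):
    print(f"{m.entity_type:6s} {m.canonical_id}  chars [{m.char_start},{m.char_end})  {m.surface!r}")

# The three-token effect wins over its one-token prefix ("dolor de
# cabeza", not "dolor"), and both the upper-case drug and the accentless
# "depresion" match their gazetteer entries.
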