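# Methods

## Pipeline model and assumptions

The package implements distant-supervision relation extraction for
drug–effect pairs in informal Spanish text. The core assumption is the
distant-supervision hypothesis: when a drug mention and an effect mention
co-occur within a bounded token window, the pair is a candidate relation,
and membership of the normalized pair in a drug–effect knowledge base is
taken as its (noisy) training label. Two well-known consequences follow
and are surfaced by the tooling rather than hidden: incomplete KBs create
false-negative labels (recall loss), and context-blind pairing creates
false-positive labels (precision loss from negation, co-reference, and
topic-separated mentions). Neither negation handling nor co-reference
resolution is implemented; they are documented error sources.

## Text processing

Tokenization is whitespace splitting with every non-word, non-space
character (including ¿ ¡) emitted as its own token; offsets are 0-based
half-open into the original text and nothing but whitespace is dropped.
No clitic splitting or sentence segmentation is attempted: forum text
defeats trained segmenters, and the kernel only needs consistent token
sequences. Normalization lowercases, folds acute accents and the
diaeresis (á→a … ü→u), preserves ñ, and collapses whitespace; it is
idempotent and is the single canonical form used by the gazetteer, the
KB name index and the kernels.

Morphology defaults to a shipped deterministic provider: a small
closed-class table (determiners, prepositions, conjunctions, pronouns,
common adverbs), coarse heuristic tags for open classes, and a rule-based
Spanish suffix-stripping stemmer (longest matching suffix, minimum stem
length 3). For open-class words lemma = stem. This is intentionally
crude — its job is to give the local kernel stable lemma/PoS/stem
features without downloads; richer analyzers plug in behind the
`MorphologyProvider` protocol.

Entity matching is leftmost-longest over normalized token sequences,
non-overlapping. A DRUG and EFFECT entry covering the same span resolves
DRUG-first (drug names are a closed nomenclature, effect vocabulary is
open lay language); the tie is logged. Token-level matching with a
leftmost-longest overlap policy is this package's choice; commercial
dictionary NER tools do not document theirs. No fuzzy matching: spelling
noise is deliberately left unsolved so its cost is measurable (see the
misspelling sweep).

## Candidates and contexts

All (drug, effect) mention pairs whose inter-mention gap — tokens
strictly between the nearer boundaries — is at most `window_tokens`
(default 250) become instances; pairs never cross messages. The window is
read as a token-gap bound rather than a sentence constraint because forum
posts lack reliable sentence boundaries. Candidate entities are replaced
by CAND_DRUG / CAND_EFFECT placeholders so the classifier learns context
rather than memorized names (which would also leak KB membership through
surfaces). Global contexts: B is the token span strictly between the
placeholders; FB prepends up to `flank_cap` (default 10) preceding tokens
and the first placeholder; BA appends the second placeholder and up to
`flank_cap` following tokens. The flank cap bounds kernel cost on
unsegmented text while mimicking sentence locality. Stop-words and
punctuation are retained throughout — they carry relational cues — and a
test guards against accidentally filtering them. Local contexts are
2·`local_window`+1 (default 5) feature bundles (token, lemma, PoS, stem)
centered on each placeholder, PAD-padded ("⊥") at message edges.

## Kernel

Each global context contributes an n-gram kernel (contiguous n-grams,
n = 1..`ngram_max`, default 3 — the standard order for this kernel
family); each local side contributes a positional count of shared feature
values (PAD matches only PAD). Components are cosine-normalized
(K/√(KxxKyy), defined as 0 when either self-kernel is 0, so an empty B
contributes 0, never NaN) before combination with equal unit weights for
FB/B/BA and configurable `weight_global` / `weight_local` (default 1.0
each); the original formulation specifies only "a linear combination", so
commensurate unit weights after normalization are this package's default.
Every component is an explicit finite inner product, hence the kernel is
symmetric and PSD by construction; tests verify both numerically. Gram
matrices are computed by sparse feature-count expansion per channel
(exactly equal, entrywise, to the pairwise kernel — asserted in tests),
with exact symmetrization of the self-Gram against float round-off.

## Classifier and evaluation

Training solves the soft-margin SVM dual on the precomputed Gram matrix
via libsvm (scikit-learn `SVC(kernel="precomputed")`), C = 1.0 by
default. Distant labels are heavily NEGATIVE-skewed, so inverse-frequency
("balanced") class weighting is the default; no negative subsampling is
performed (exposed as a caller decision). Prediction labels POSITIVE on
strictly positive decision values; an exact zero is NEGATIVE. The
message-level 75/25 split is a seeded shuffle taking
floor(train_fraction·N) ids — at N = 84,090 this yields 63,067 / 21,023.
Evaluation is per relation instance: TP/FP/FN with precision, recall and
F1 at full precision (2-decimal rounding only at display), 0 by
convention for empty denominators. The classifier label is binary
(related / not-related); ADR vs indication is carried as KB metadata
only, since the evaluation regime this mirrors reports a single confusion
table. Gold evaluation aligns candidate instances to BRAT-standoff
relation annotations by mention character spans.

## Synthetic data generator

The generator emulates the study's data shapes: short informal messages
with a controllable category mix (defaults: 55% with neither entity, 27%
effect-only, 5% drug-only, 13% both — the profile reported for real
patient-forum traffic), pseudo-Spanish drug names (syllable-sampled,
nomenclature suffixes like -ol/-ina/-azol, occasionally accented) and
1–3-word lay effect phrases, unique after normalization and disjoint from
all template/filler vocabulary so gazetteer self-recall is exactly
measurable. A complete KB is built by sampling each (drug, effect) pair
as related with probability `relation_density` (default 0.3), typed
ADR/INDICATION at 0.92/0.08 to echo the heavy ADR skew of real
drug-leaflet resources. Messages embedding a truly related pair use a
positive-cue template ("… me provoca …"); unrelated pairs get neutral or
negated templates, so gold labels coincide with KB membership by
construction and distant labeling is exact under the complete KB
(verified as an invariant). Because matching is already accent/case
insensitive, no redundant accent/case variant rows are added to the
generated gazetteer. Default corpus size is 400 messages (the scale of a
hand-annotatable gold corpus); classifier tests use ~1,100 messages with
an enriched "both" rate to obtain ≥500 candidate instances.

Misspelling noise applies at most one character edit per mention
(substitute / drop / duplicate a character, or strip an accent — all
Levenshtein distance 1), never the first character, with probability
`misspelling_rate` (default 0.1). Per-mention random draws are consumed
in a fixed order independent of the rate, so for a fixed seed the edited
set at a lower rate is a subset of that at a higher rate with identical
edits — mention recall is therefore non-increasing in the rate by
construction, which is the property the sweep tests assert. What the
generator does **not** model: real Spanish grammar, lexical variation
(depresión/depremido), abbreviations ("depre"), drug-name ambiguity with
common words, emoticons/slang, and co-reference. Passing tests therefore
demonstrate the correctness of the machinery and its stated sensitivities
(KB incompleteness, spelling noise), not performance on real forum text,
where dictionary coverage and lay phrasing dominate the error budget.

## Numerical and design choices

- Coordinates are 0-based half-open everywhere (characters and tokens).
- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; KB subsampling iterates relations in a stable sort order so
  results never depend on set iteration order.
- Duplicate gazetteer terms collapse first-id-wins with a logged warning;
  duplicate KB triples collapse silently.
- KB name resolution prefers the gazetteer canonical id over surface
  lookup, since gazetteer and KB may disagree on preferred names.
- The KB-incompleteness invariant is measured at the distant-labeling
  stage (labels vs synthetic gold), where the recall drop is a
  deterministic consequence of removed relations; a retrained classifier
  can partially generalize past missing KB entries, so end-to-end recall
  is not guaranteed to fall strictly.
- Test and acceptance problem sizes (200–1,100 messages, ≤ ~600
  instances) keep Gram matrices small enough that the whole suite runs in
  seconds while still exercising every stage at realistic density.

## Known limitations

Dictionary-only NER (no fuzzy matching, no disambiguation), no negation
or co-reference handling, a deliberately coarse default morphology, and a
synthetic corpus whose separability is optimistic relative to real forum
text. The SL-kernel coefficients and n-gram order are configurable
because the original configuration is not fully specified; defaults are
stated above.
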