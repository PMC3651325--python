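# Methods

This note documents the models and procedures implemented in `bioner`, the
choices made where the design was genuinely open, and what the synthetic
test corpora do and do not show about real data.

## Tokenization

Base segmentation splits on whitespace (a pluggable hook lets an external
biomedical tokenizer supply coarse spans instead), then a refinement pass
makes every punctuation character its own token.  In particular every word
containing `/`, `-` or `.` is broken apart, because gene names glued to
qualifiers ("BRCA-1/2") otherwise leave sub-spans like "BRCA-1"
inexpressible at the token level, turning them into systematically wrong
negative examples during training.

Two deliberate uniformities: separators become standalone tokens (rather
than attaching left or right), so both "BRCA-1" and "1/2" remain token
ranges; and `.` splits even inside decimals ("2.5" → `2 . 5`).  The rule is
stated without exceptions on purpose — annotations re-align by character
offset regardless, and a uniform rule is predictable.  `retokenize` applies
the same refinement to externally tokenized input and remaps annotations by
character span; a span that still crosses a token boundary afterwards is an
error, never silently widened.

## Feature extraction

Per-token features are string-valued (`NAME=value`), deduplicated,
order-preserving, and a pure function of (sentence, configuration).
Families and defaults:

* **Orthographic** (13 boolean patterns): initial capital, all capitals,
  all lowercase, mixed case, single character, all digits, contains
  digit/hyphen/slash/period/other symbol, Roman numeral (standalone I–X),
  Greek letter word (alpha…omega).  The inventory is this package's
  canonical set; each pattern is individually toggleable.
* **Affixes**: prefixes and suffixes of lengths {2, 3, 4} (suffixes such as
  "ase", "ome", "gen" are characteristic of gene/protein names).  Lengths
  are configurable; the defaults cover the common English morpheme lengths
  without exploding the feature space.
* **Character n-grams** of sizes {2, 3, 4}, finding shared substrings in
  the middle of tokens too.
* **Word shapes**: type I replaces digit runs by `*` ("Abc1234" → "Abc*");
  type II maps every character to its class ("Abc:1234" → "Aaa#1111");
  type III collapses class runs ("Abc:1234" → "a#1").
* **Linguistic**: the token itself plus lemma, POS tag and BIO chunk tag
  when present.  These attributes come from an external linguistic
  processor (or the synthetic generator); the package does not ship a
  parser.
* **Dependency**: lemmas of entity-indicative syntactic neighbours —
  governing verbs of subjects and objects, modified nouns, and modifiers.
  Off by default since it needs a dependency parse.
* **Local context**: *windows* copy a neighbour's features with an
  `@offset` marker — window sources are feature-name prefixes, so
  domain-knowledge matches travel through windows as `LEXICON`/`TRIGGER`
  sources just like `TOKEN` or `LEMMA`; *conjunctions* join attribute
  values of several relative positions into one feature.  Default conjunction specs are
  {-3,-1}, {-2,-1}, {-1,0}, {-1,1}, {0,1} with lemma and POS as two
  separate streams (mixing them in one feature would square the
  vocabulary).  For the symmetric spec {-1,1} the token's own value (offset
  0) is *excluded*: the canonical conjunction for "neonatal" in
  "…aspects of neonatal hyperbilirubinemia." is
  `LEMMA=of@-1_&_LEMMA=hyperbilirubinemia@1` — offset 0 participates only
  where it is an endpoint of the spec.

## Lexicons

Entity-name lexicons are expanded into orthographic variants before
matching: space↔hyphen swaps; separator removal; hyphen insertion at
letter→digit boundaries; standalone Roman numerals I–X → Arabic and Arabic
1–9 → Greek letter words; and `h`-prefix/`p`-suffix for acronyms (all
capitals, length 2–5 — the threshold is configurable since "acronym" has no
universal definition).  Each rule applies once to the base name; no
fixed-point iteration, keeping the expansion bounded and deterministic.

Matching is greedy longest-match, left to right, over token subsequences
joined three ways: single spaces, no spaces, and with space/hyphen
separators stripped (pairing with the separator-removal rule so a
hyphen-split "IL - 2 receptor" still finds "IL-2 receptor").  Entries of at
most 3 characters match case-sensitively — short gene symbols collide with
ordinary words ("AR", "WAS") — longer entries case-insensitively; both
thresholds are exposed.  Matched tokens receive `LEXICON=<name>`; trigger
lexicons (single-word domain terms like "activation") match by exact lemma
and emit `TRIGGER=<name>`.

## CRF engine

The linear-chain CRF is implemented in-package on numpy/scipy: log-space
forward–backward, Viterbi decoding, and L-BFGS maximization of the
L2-regularized conditional log-likelihood (default penalty weight 1.0, at
most 500 iterations; the library defaults here use 150, which the convex
objective reaches comfortably at the corpus sizes involved).  The objective
is convex and optimization starts from zero, so training is deterministic;
the seed is recorded for provenance.  Unseen features at tagging time are
ignored (they have no learned weight).

**Confidence scores.**  Two levels, both from standard forward–backward
quantities: the sentence confidence is the posterior probability of the
Viterbi path, `p(ŷ|x, λ)`; the per-annotation confidence is the product
over the annotation's tokens of the posterior marginal of the predicted
label.  The two levels feed the two combination modes respectively.

**Backward direction.**  The token sequence (with its annotations and
arcs) is reversed before feature extraction and training, so `B` marks the
reading-order-*last* token of each entity and the learned transition
structure genuinely differs from the forward model — reversing tag strings
alone would not change it.  Predictions are un-reversed and re-normalized
to standard BIO.

**Order-2 emulation.**  Second-order label dependencies are obtained
exactly on the first-order chain by expanding labels to (previous, current)
pairs.  The virtual previous label at sentence start is `O` — a sentence
begins outside any entity — giving exactly L×L pair labels.  Predicted
pairs are projected back to their current component and BIO-repaired.
Current-label marginals are obtained by summing pair marginals sharing a
current component.

**BIO repair.**  Decoding never rejects a tag sequence: `I` after `O`
opens an entity, and an `I` with a new type closes and reopens.  Tagger
output is therefore always decodable.

## Model combination

Same-class ensembles: if the models' annotation sets overlap anywhere in a
sentence, the entire sentence is taken from the model with the highest
sentence confidence; with no overlap the union is returned (the
all-disjoint case is underdetermined in the combination rule as usually
stated; union keeps every independently found mention).  Multi-class
ensembles: annotations are clustered by transitive character-span overlap
and each cluster keeps its highest per-annotation confidence member;
singleton clusters pass through.  Ties break deterministically (earlier
start, earlier end, lexicographically smaller type; for whole-sentence ties
the lexicographically smallest annotation set), making both combiners
invariant to model order.  Overlap is defined on character spans, not token
indices, so taggers that disagree on tokenization still compete.

Model-set selection is a configuration input chosen on development data;
selecting the ensemble on test results is deliberately unsupported, to
avoid test-set leakage by construction.

## Post-processing

*Bracket parity*: an annotation whose text contains an odd count of round,
square or curly brackets is removed.  Parity is per bracket type — pooling
would let `(]` pass.  A boundary-adjusting variant (move the span to the
nearest balancing bracket instead of removing) is implemented behind an
off-by-default flag; removal performs better and is the default.

*Abbreviation resolution*: for each parenthesized short-form candidate
(default minimum length 2 — single letters are too ambiguous; the bound is
configurable), the preceding window of min(|SF|+5, 2·|SF|) tokens (the
classic recognizer's bound) is searched for the shortest long form whose
first word anchors the short form's first character, aligning the remaining
characters in order, and satisfying: (a) first characters agree, (b) the
long form is longer, (c) the long form does not contain the short form.
If exactly one form of a pair is annotated, the other gains an annotation
of the same type; a partially covered form is extended to the full form.
Conflicting types across the two forms leave the pair unchanged with a
warning.  Propagation is idempotent and never removes annotations.

## Evaluation

Exact matching on (sentence, whitespace-normalized character span, type);
the span is counted over non-whitespace characters so differently tokenized
predictions compare fairly.  P, R and F1 use the zero-denominator → 0
convention.  Multi-class reports give per-class rows plus a micro-averaged
overall row (pooled TP/FP/FN).  Alternative-annotation credit accepts a
prediction matching any registered alternative span of a gold annotation,
each gold creditable once and each prediction consumed once.

## Corpus dialects

The offset dialect counts **non-whitespace** characters with inclusive
ends; internal offsets are 0-based half-open over raw text.  Conversion
happens only in the readers/writers, so the two conventions cannot mix
silently.  Annotations that fail text-slice equality or do not align to
token boundaries are errors, not silently widened — the tokenizer's split
rule exists precisely to make such spans representable.  The IOB2 dialect
(token TAB tag, blank-line sentence separators, optional `###MEDLINE:` doc
separators) round-trips byte-identically in canonical form.

## Synthetic corpora

The generator emulates the statistical structure the features target:
entity names `<CapitalizedStem><suffix>` with an optional `-digit`
qualifier, suffixes drawn from a per-type vocabulary ("ase", "ome", "gen",
…); trigger words adjacent to entities (before or after with equal
probability, keeping the corpus left-right symmetric so forward and
backward models face the same problem); abbreviation patterns
`long form ( SF )` built from word initials so the recognizer's constraints
hold by construction; stray unbalanced brackets as noise; and an open
vocabulary of random lowercase filler stems alongside a small closed
function-word/verb/noun list, so held-out entity *and* filler tokens are
largely unseen — token identity alone must not suffice.  Tokens carry
synthetic lemma/POS/chunk attributes so linguistic and conjunction features
operate.

Default rates: entity 0.2 per content slot, trigger 0.5, abbreviation 0.15
per sentence, bracket noise 0.05, hyphen-digit qualifier 0.4, sentence
length 6–12 slots.  These give roughly 1–2 entities per sentence with
enough contextual signal for a few hundred sentences to train on — small
enough for desk-scale experiments, rich enough that feature ablations are
observable.

**What passing tests show.**  The planted regularities are exactly the
ones the features detect, so learning-sanity results (held-out F1, ablation
drops, direction/order bands) demonstrate that the pipeline wiring —
features → CRF → decoding → scoring — is correct, not that any particular
score would be reached on real corpora.  Real biomedical text has heavier
ambiguity, annotation inconsistency and vocabulary drift than the
generator emulates; scores on the standard gene-mention corpora require
those corpora and an external linguistic preprocessor, which this package
consumes but does not ship.  The study sizes used by the test suite and
the acceptance script are 200 training and 50 held-out sentences, with
150 L-BFGS iterations — chosen as the smallest sizes at which the planted
structure is reliably learned.

## Known limitations

* No sentence splitting and no Unicode normalization; input is one
  sentence per line.
* Lemma/POS/chunk/dependency annotations must be supplied (file columns,
  a pluggable provider, or the synthetic generator); no bundled parser.
* The bundled lexicons are small synthetic samples for tests and examples,
  not curated resources.
* Evaluation implements exact matching (plus alternatives credit) only;
  no partial-credit variants.
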