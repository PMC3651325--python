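# Training configuration for a forward first-order gene/protein tagger
# on an offset-dialect corpus (see `bioner generate` for a synthetic one).
corpus:
  dialect: offset
  sentences: corpus/sentences.txt
  annotations: corpus/annotations.txt
entity_types: [PRGE]
features:
  # feature families (all shown with their defaults except dependency,
  # which needs externally supplied parses)
  token: true
  lemma: true
  pos: true
  chunk: true
  orthographic: true
  prefix_suffix: true
  ngrams: true
  shape_i: true
  shape_ii: true
  shape_iii: true
  dependency: false
  lexicon: true
  trigger_words: true
  conjunctions: true
  windows: false
  affix_lengths: [2, 3, 4]
  ngram_sizes: [2, 3, 4]
  conjunction_windows: [[-3, -1], [-2, -1], [-1, 0], [-1, 1], [0, 1]]
  conjunction_sources: [lemma, pos]
model:
  order: 1            # 1 or 2 (2 is emulated by label-pair expansion)
  direction: forward  # forward | backward
  c2: 1.0             # L2 regularization weight
  max_iterations: 150
  seed: 0
# optional lexicons:
#   - {path: my_genes.txt, name: PRGE}
#   - {path: my_triggers.txt, name: TRIGGER, trigger: true}
output: model
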