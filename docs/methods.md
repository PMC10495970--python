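# Methods

This note documents the models, procedures, parameter choices and known
limitations of `synthaction`.  It is the design record: anything numeric
claimed here is computed by the test suite or by `scripts/acceptance.py`,
not asserted from memory.

## Problem setting

Patent documents mix synthesis procedures with formulation, property and
mechanism text.  Two learned stages turn them into a tabular reaction
dataset:

* **Task 1 — paragraph classification.** Binary decision: is this paragraph
  a well-formed organic synthesis procedure?  Before any learning, five
  admission rules (R1–R5, below) define what "well-formed" means.
* **Task 2 — sentence conversion.** Map each procedure sentence to a
  structured clause sequence in a 28-action formal language
  (`docs/grammar.md`), e.g. `MAKESOLUTION with … ; ADD SLN; STIR at 25 °C
  for 2 h.`

Downstream, reactants are read off ADD/MAKESOLUTION clauses, the product
off the first YIELD clause, solvents are removed via a stoplist, and names
are resolved to SMILES through a local dictionary.

## Admission rules (R1–R5)

R1 word count ≥ 10 (whitespace tokens; numbers count as words).
R2 the paragraph must end with terminal punctuation, optionally followed by
   a closing quote/bracket.  "Ends abruptly" is operationalized as exactly
   this check — no finite-verb heuristic — to keep the rule deterministic.
R3 no reference phrases ("following general procedure", "as described in",
   …); case-insensitive substring match over a configurable list.  The
   shipped list seeds from published examples and is a config file, not a
   closed set.
R4 no numbered compound references (Compound/Intermediate/Example + number).
   A negative lookahead keeps the rule from firing on numbered chemical
   names ("compound 1-benzyl-2-(chloromethyl)pyrrolidine").
R5 product euphemisms ("title compound", "white solid", …) are admissible
   only if an IUPAC-looking name occurs **in the same sentence** — the
   closest testable reading of "the product may be referenced if the proper
   compound name is also provided".

`looks_iupac` scores three feature families — digit locants ("3-", "2,3-"),
bracket nesting inside a token, and nomenclature morphemes (a hit counts
only when ≥ 2 morphemes co-occur) — plus densely hyphenated numeric tokens;
≥ 2 features ⇒ IUPAC-like.  It is a heuristic for rule R5, not a validator
of chemical correctness.

## Synthetic corpus generator

The generator defines the study conditions for every learning test.

* **Clause templates.** 37 templates cover all 28 actions, each coupling a
  sentence pattern to a structured pattern over shared slots.  Sentences
  chain 1–3 clauses with the connective ", then ".  Because each template is
  a (format, regex) pair, the template set is invertible:
  `rule_oracle_translate` is the deterministic inverse used as the
  converter-independent pipeline path, and `oracle ∘ generator ≡ identity`
  is asserted over generated corpora.
* **Action distribution.** Default sampling weights are the per-action
  frequencies of the large patent-derived corpus this emulates (Add
  2,249,260 … Sonicate 1,447).  A seeded 20,000-pair draw reproduces each
  action's relative frequency within ±10% wherever the expected count is
  ≥ 1,000 (below that, relative error is sampling noise by construction).
* **Lexicons.** 114 compounds, 24 solvents, 4 temperature notations, 8
  duration units, plus quench/drying/gas lists, shipped as editable text
  files.  Amounts, temperatures and durations draw from fixed realistic
  value lists ("374 mg", "25 °C", "16 h", "room temperature", "overnight").
* **Classification sets.** Positive fraction defaults to 0.336 (the class
  balance of the emulated labeled corpus); positives are 2–4 chained
  procedure sentences, negatives come from six template families each
  violating a specific admission rule, so every negative fails
  `admissible_procedure` by construction.
* **Augmentation.** The four operators substitute temperature, duration,
  solvent, or compound surfaces, identically in sentence and structured
  sides (slot provenance makes this exact), at most 4 variants per
  instance.  Variants never change the action-type sequence.
* **Split rule.** validation = round(0.1 N), test = round(0.1 N), train =
  remainder.  This reproduces both published partitions — 20,199 →
  (16,159, 2,020, 2,020) and 3,074,038 → (2,459,230, 307,404, 307,404) —
  and is asserted by tests.  Python's banker's rounding decides exact .5
  ties; neither published size exercises such a tie.

**What the generator does not emulate:** real patent prose variety
(anaphora, OCR noise, free word order), open-ended chemical vocabulary,
annotation noise, and the ambiguity that motivates lenient parsing.  Tests
passing on this corpus demonstrate that the pipeline, models and metrics
are implemented correctly and that the architectures can learn the mapping;
they do not certify accuracy on real patents.

## Subword tokenizer

A unigram-language-model segmenter with a fixed vocabulary shared between
source sentences and structured targets (enabling tied embeddings):

* seed inventory = corpus substrings (≤ 10 chars) ranked by count × length;
  hard-EM (Viterbi counts) re-estimates piece log-probabilities; the
  inventory is pruned by usage until the budget (vocab − 4 control − 256
  byte pieces) is met.  Training is fully deterministic.
* **Byte fallback** guarantees every input round-trips:
  decode(encode(s)) = s for any single-spaced text, asserted over generated
  corpora and fuzzed unicode.
* **Digits.** With `split_digits=False` (default) complete digit runs are
  protected from pruning and the Viterbi search refuses boundaries inside a
  run whenever a whole-run segmentation exists, so "374" is one piece
  rather than three.
* **Case is preserved**: action keywords are uppercase in targets and
  chemical nomenclature is case-significant, so lowercasing would destroy
  signal.  No unicode normalization is applied by default.
* Mean pieces-per-word decreases monotonically with vocabulary size on a
  fixed corpus (asserted at 500/1000/2000).

## Neural models

All models run on `synthaction.nn`, a compact float32 reverse-mode autodiff
core over numpy (fused LSTM/GRU cells, multi-head attention, layer norm,
the five optimizers SGD/RMSprop/Adam/Adamax/Nadam).  Single-threaded numpy
makes seeded runs bitwise reproducible.  Gradients are verified against
central differences in the test suite.

* **Classifier.** Embedding → dropout → GRU/LSTM/BiLSTM (masked final
  state; the BiLSTM concatenates both directions) → ReLU feed-forward →
  1-unit output.  The transformer variant mean-pools non-pad positions
  after the attention blocks (pooling is a design choice; the published
  description does not specify it).  Loss is binary cross-entropy with the
  positive class weighted by the *importance* factor (published search
  interval 0.5–3.0); recall of the positive class is non-decreasing in
  importance on an imbalanced set (5-seed check).
* **Seq2seq.** The recurrent converter is an encoder–decoder **without
  attention**: the encoder's final state is the fixed-length context vector
  (the BiLSTM variant bridges the concatenated directions through a linear
  layer).  This implements the described architecture exactly and inherits
  its known long-input limitation.  The transformer uses pre-norm blocks,
  sinusoidal positions, shared source/target embeddings and a tied output
  projection.  Teacher forcing with token cross-entropy; no label smoothing
  or length penalty (defaults where the source is silent).
* **Early stopping.** Training halts when the validation metric (accuracy
  for the classifier, token accuracy for seq2seq) has not improved in
  `patience` epochs (default 7); the best epoch's weights are restored, and
  `stopped_epoch − best_epoch == patience` whenever stopping fires early.
* **Decoding.** Greedy by default (deterministic); beam (width 4, mean
  log-probability length normalization) optional.  Transformer greedy
  decoding uses an incremental key/value-cached forward pass that is
  token-for-token identical to the teacher-forced decoder.
* **Presets.** The published full-scale optima (Tables of hyper-parameters
  for GRU/LSTM/BiLSTM/transformer classifiers and LSTM/BiLSTM seq2seq, and
  the 6-stack/8-head/512/2048 translation transformer at learning rate
  0.005) load and validate but are impractical without accelerators.  Desk
  presets are the package's own working scale: classifier BiLSTM
  (vocab 2,000, embedding 8, hidden 16, FF 8, importance 2.0, Adam,
  batch 64, ≤ 20 epochs, inputs truncated to 64 pieces) and seq2seq
  transformer (2 stacks, 4 heads, model dim 128, FF 256, Adam 1e-3,
  batch 96, 5 epochs, max source/target 96/88 pieces).  Gradient clipping
  at global norm 5 stabilizes both.

## Evaluation

* Random baseline = Σ P(y)², majority baseline = max P(y).  From the
  documented 0.664/0.336 class distribution these give 0.5538 (printed
  truncated as 0.553) and 0.664.  Note the distribution is taken from the
  stated percentages; the separately printed raw label counts imply a
  different ratio — the percentages are authoritative here, and the
  discrepancy is simply documented.
* Classification metrics use the standard confusion-matrix formulas with
  class 1 positive; zero denominators return 0 and are flagged.
* **BLEU** is corpus-level: clipped n-gram counts (N = 4) pooled over
  segments, uniform-weight geometric mean, brevity penalty e^(1−r/c) for
  c ≤ r with r, c corpus-total token counts.  **No smoothing** by default —
  any zero pooled precision scores 0 — matching the printed formula; a
  smoothing epsilon exists but is off everywhere tests assert values.
  Tokenization is whitespace on normalized text for both metrics.
* **ROUGE-L** is the β = 1 LCS F-measure; the corpus score is the
  arithmetic mean of per-pair scores (an explicit choice — only the
  per-pair formula is published).
* **Exact match** compares strings after surface normalization (collapsed
  whitespace, `"; "` separators, single trailing period), so a missing
  final period alone is not an error.
* Oracle checks: BLEU agrees within 1e−6 with an independently coded
  Counter-based implementation on 200 random corpora; the ROUGE-L dynamic
  program agrees exactly with brute-force subsequence enumeration,
  exhaustively for all 3-symbol strings up to length 3 (≈ 1.6 k pairs) and
  on seeded random samples of lengths 4–8 (full enumeration of all ≈ 10⁸
  length-≤8 pairs is not tractable; the sampled domain is fixed by seed).

## Extraction and pipeline

* Reactants: ADD + MAKESOLUTION chemicals, order preserving, SLN skipped,
  first occurrence kept on duplicates, stoplist removal case-insensitive
  and robust to trailing abbreviation parentheticals
  ("tetrahydrofuran (THF)").  The shipped stoplist covers the solvent
  lexicon plus brine; users edit it as a plain file.  MAKESOLUTION solvents
  are excluded via the stoplist only — no positional rule.
* Product: first YIELD clause; additional YIELDs log a warning.
* Name→SMILES: local two-column TSV dictionary, case-insensitive lookup;
  unresolved names are kept with a flag, never dropped
  (|output| = |input| always).  Network name-resolution services are out of
  scope by design; a resolver can be plugged in by extending
  `NameDictionary`.
* Sentence splitting is rule-based: split at [.!?] + whitespace +
  uppercase/digit/open-paren, never inside parentheses, guarded by a
  configurable abbreviation list; "°C." therefore splits exactly when an
  uppercase sentence start follows.  Spans are 0-based half-open.
* Paragraph-level structured output joins sentence-level clause lists with
  `"; "`.  Records whose merged string fails strict parsing are quarantined
  to an errors list; translations containing INVALIDACTION or
  FOLLOWOTHERPROCEDURE are excluded by default (`exclude_invalid`), since
  such content is either not a real operation or points outside the text.
* Stage counts are monotone non-increasing and reruns are byte-identical
  for a fixed config and seed.

## Problem sizes used by tests

Unit tests use corpora of 32–1,500 pairs and 400-paragraph classification
sets with vocabularies of 400–1,000.  The two training acceptance checks
use the package's study conditions: a 4,000-paragraph classification set
(5-seed BiLSTM ensemble, compared against that set's majority baseline)
and a 20,000-pair conversion corpus (80/10/10 split, desk transformer,
BLEU and exact match on the held-out tenth).  The acceptance script's
quantities are analytic and run in well under a second.

## Known limitations

* The recurrent seq2seq's fixed-length context vector degrades on long
  inputs; this is faithful to the described architecture, not a defect to
  fix here.
* Beam search re-runs the decoder per hypothesis (no batched beam); it is
  intended for inspection, not bulk decoding.
* `looks_iupac` is a feature heuristic; adversarial phrases can fool it in
  both directions.
* The unigram trainer uses hard-EM (Viterbi counts) rather than full
  forward–backward expectations and prunes by usage rather than exact
  likelihood loss; segmentations are deterministic and round-trip-exact,
  but piece inventories need not match other unigram implementations.
* Byte-fallback round-trips arbitrary text, but words absent from the
  training distribution may segment into many pieces, inflating sequence
  lengths.
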