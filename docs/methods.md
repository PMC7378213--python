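# Methods

This note documents the models and procedures implemented in `varpanel`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic benchmarks do and do not show.

## Document model and segmentation

Articles are segmented into paragraphs (blank-line blocks), sentences
(rule-based split on `[.!?]` followed by whitespace and an
uppercase/digit start, with an abbreviation stop-list) and tokens.
Tokens are maximal alphanumeric runs that may contain internal `.`,
`>`, `-`, `/`, `+`, `_`; this keeps variant surfaces such as `c.123A>G`,
`p.Ala123Val` and `rs12345` intact as single tokens, which the
recognizers and all distance computations rely on. Character offsets are
0-based half-open into a single `full_text` string and are enforced at
construction time (every token's surface must equal the substring at its
span). Title and abstract are segmented like body paragraphs and carry a
section flag; keyword coverage deliberately counts **body** tokens only,
since the triage criterion is about the full body of an article.

PubTator standoff annotations index `title + " " + abstract`; the reader
translates those offsets into `full_text` coordinates, verifies the
surface string, and rejects (with a counter) any annotation that does
not match. External annotations take precedence over the built-in
recognizers on a per-document basis: the package must both interoperate
with dedicated taggers and stand alone.

## Relevance filter

- **Keyword weight** = relative document frequency in the
  variant-positive sample. The weighting scheme of the original word-cloud
  construction is not fully specified anywhere we could follow, so the
  simplest frequency definition is used and kept on the list for
  reporting; an optional weighted-coverage mode exists but is not the
  default.
- **Coverage** = fraction of keyword *types* present in the body
  (unweighted), matched case-insensitively; the relevance criterion is
  `coverage >= 0.10`, inclusive at the boundary.
- Defaults: `top_k = 500`, `min_df = ceil(0.05 · n_source_docs)`,
  packaged English stopword list, pure-number tokens dropped, ties broken
  lexicographically. These control list size and stability, not the
  threshold semantics.

## Entity recognition

The built-in variant recognizer is deliberately narrower than a full
mutation grammar: HGVS protein substitutions (1- and 3-letter), bare
substitutions, HGVS nucleotide substitutions and simple
del/dup/ins forms, and rsIDs. Matching is token-aligned, so patterns
never fire inside longer words. Two false-positive guards apply to bare
`Letter-Number-Letter` matches: both letters must be valid amino-acid
codes with reference ≠ alternate, and a match whose two preceding tokens
include a figure/table/chemical cue word is suppressed. Normalization
collapses all protein-substitution spellings onto `p.<ref><pos><alt>`
with one-letter codes, lowercases rsIDs and nucleotide prefixes, and is
idempotent (property-tested over the grammar it accepts).

Gene/disease tagging is dictionary-based, longest-match-first and
non-overlapping. Gene symbols of length ≤ 4 are matched case-sensitively
(`WAS`, `KIT` collide with common words); all other terms match
case-insensitively.

## Association scoring

- **Distance unit**: tokens strictly between the two spans; adjacent or
  overlapping mentions have distance 0. "Word count" is not defined more
  precisely by the protocol this implements, and strict between-count is
  the least ambiguous choice.
- **Variant–gene linking**: nearest gene with tier priority same
  sentence ≻ same paragraph ≻ document; within a tier smallest distance,
  ties to the preceding gene, then smaller offset. Pairs not found in the
  coordinate resolver are marked UNRESOLVED and never reach panels; they
  are counted as eliminated false positives. Whether unresolved pairs
  should still contribute variant–disease edges was an open choice; here
  they do not.
- **Candidate collection**: for each of the k occurrences of a variant's
  canonical key, the closest disease mention wins (ties: preceding, then
  smaller offset). Note this is a pure distance rule with no tier
  preference — by design, since the tiers enter through the score.
- **Scoring**: `total = SSO + SPO + SS` with SSO ⇒ SPO by construction,
  so `total ∈ [−1, 3]`. SS is computed on the text strictly between the
  spans (mention tokens excluded); text after both mentions can never
  change a score.
- **Sentiment**: a small packaged valence lexicon (~40 terms with values
  in [−0.4, 0.4]); SS = mean valence of matched tokens, sign-flipped when
  a negator (`not/no/never/without`) occurs within the three preceding
  tokens, clamped to [−1, 1], 0.0 for text with no hit. This is a
  deliberate, transparent reimplementation of lexicon polarity scoring —
  not a port of any particular sentiment package — and the lexicon file
  is swappable.
- **Aggregation across occurrences**: a disease's score is the maximum
  of its per-occurrence totals by default (`sum` available). The
  protocol's "highest disease association score" does not say whether
  scores accumulate over the k appearances; max is the more conservative
  reading and is the default. Ties break by more supporting occurrences,
  then earlier first mention, then identifier.
- **Baseline**: number of sentences containing both variant and disease,
  argmax, same tie-breaks, no fallback when nothing is co-sentential.

## Evaluation

Predictions and gold are compared as sets of
(doc_id, canonical variant, disease id); both sides pass through the same
normalizer and no surface-form credit is given. Matching is per-document
by default with a corpus-global option. Degenerate denominators yield 0.0
with a flag. F1 is reported at five decimals where benchmark tables are
involved, matching their print precision.

## Panel validation

- **Cross-cohort AUC**: train on ONE dataset, test on each of the rest —
  n·(n−1) rounds, not k-fold — using a random forest
  (500 trees, scikit-learn defaults otherwise, fully seeded; the tests
  assert the contract — scores in [0, 1], determinism given seed — rather
  than internals). Round features are panel genes present in both
  cohorts; rounds with zero overlap are skipped with a warning. Mean and
  median AUC are both reported because cohort-rotation studies typically
  highlight the median.
- **DEG comparator**: per-gene Welch t-test (the underlying protocol
  never names its test; Welch is the robust default and the test is
  configurable), Benjamini–Hochberg adjustment, inclusion iff adjusted
  p < 0.05 **and** |log2 fold change of class means| ≥ 1.5. Non-positive
  class means are floored at 1e−9 so the fold change stays defined.
- **Enrichment**: hypergeometric upper tail P(X ≥ overlap) with
  population = universe size, successes = panel size, draws = pathway
  size; ranking by ascending p, ties by larger overlap then name. The
  implementation uses the SciPy survival function and is checked against
  exact combinatorial enumeration in the tests.
- **Overlap check**: percentage of panel genes measured per cohort, with
  a warning when the average drops below 80% — below that, much of the
  panel cannot contribute features.

## Synthetic data: what it emulates, and what it does not

The corpus generator plants one variant association per variant article
(configurable): a variant surface drawn from a format mix
(30% bare 1-letter, 20% 3-letter, 20% HGVS protein, 15% HGVS nucleotide,
15% rsID), a gene mention in the same sentence, and the gold disease
either co-sentential (60%), co-paragraph (30%) or in an adjacent
paragraph (10%). Two distractor diseases per article occupy earlier,
distant paragraphs; with probability 0.3 a distractor instead gets an
explicitly negated sentence containing an extra occurrence of the variant
("… was not associated with …"), the configuration that misleads
co-occurrence counting while the polarity term keeps the composite score
low. Gold sentences carry positive connective phrasing at rate 0.8.
Figure/table decoy labels with the Character-Number-Character shape are
inserted next to cue words at about one per article. Background articles
draw from a disjoint vocabulary with 5% topical leakage. Distractor
blocks are separated from the gold sentence by a filler paragraph so the
gold disease remains the *closest* mention for the gold occurrence; the
adversarial pressure is exerted through scoring, not through corrupting
the closest-disease pre-selection. These rates were fixed once as a
plausible difficulty profile and are all exposed on `CorpusConfig`.

Expression cohorts share per-gene baselines (uniform on [1, 2]) across
cohorts, add `effect_size` (default 3.0) to panel genes in disease
samples and Gaussian noise (`noise_sd` = 1.0), with 30 samples per class
per cohort. The default effect corresponds to a ~2.5–4× fold change, so
the DEG comparator recovers a meaningful subset of panel genes.

Limitations of the emulation: generated text is templated word salad, not
scientific prose — recognizer performance on it says nothing about recall
on real full text, where surface variety, hedging and cross-sentence
anaphora dominate errors. Expression cohorts have no batch effects,
platform differences or confounded covariates, so cross-cohort AUC here
is an upper bound on what heterogeneous real cohorts would give. Passing
tests demonstrate the machinery is correct and the score ordering is real
under the planted mechanism; they do not certify field performance.

## Problem sizes in the test and acceptance runs

Benchmarks run at desk scale, chosen so the full suite completes in a few
minutes on one CPU: 200 variant + 200 background articles for the
relevance separation, 200 variant articles for the method comparison,
60 articles for exact end-to-end recovery, two 60-sample cohorts × 20
seeds for the planted/null AUC distributions, 50 replicates for DEG
type-I control, and complete enumeration of hypergeometric instances up
to universe 30.

## Known limitations

- Gene and disease lexicons are small packaged fixtures (50 symbols,
  20 disease names); real use requires supplying full lexicons as
  two-column TSV.
- The variant grammar omits frameshifts, complex indels and IVS
  notation; coordinate resolution is a static lookup table, not a live
  recoder service.
- The sentiment lexicon is tuned for association-claim polarity, not
  general sentiment; swapping in a larger valence table is supported but
  unvalidated.
- Disease assignment picks exactly one disease per variant per document;
  genuinely multi-disease articles are truncated to the top-scoring
  association.
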