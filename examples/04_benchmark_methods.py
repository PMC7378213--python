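"""Compare the composite scorer with the sentence co-occurrence baseline.

Generates a corpus where distractor diseases occupy distant sentences
(some explicitly negated next to an extra variant occurrence) and gold
pairs are co-sentential or co-paragraph.  The composite score
(same-sentence + same-paragraph + between-text sentiment) resists the
negated distractors; plain co-occurrence counting does not, and also
cannot assign anything when the gold pair is only co-paragraph.
"""

from varpanel.evaluation import GoldStandard
from varpanel.pipeline import evaluate_against_gold, extract_from_documents
from varpanel.synthetic_data import CorpusConfig, generate_corpus

config = CorpusConfig(
    n_variant_docs=200,
    n_background_docs=0,
    distance_distribution=(0.6, 0.4, 0.0),
)
docs, truth = generate_corpus(config, seed=101)
result = extract_from_documents(docs, resolver=truth.resolver)
gold = GoldStandard(pairs=truth.gold_pairs())
proposed, baseline = evaluate_against_gold(result, gold)

print(f"{'':12s}{'precision':>10s}{'recall':>10s}{'F1':>10s}")
print(f"{'composite':12s}{proposed.precision:10.5f}{proposed.recall:10.5f}{proposed.f1:10.5f}")
print(f"{'baseline':12s}{baseline.precision:10.5f}{baseline.recall:10.5f}{baseline.f1:10.5f}")
print(f"\nF1 advantage of the composite scorer: {proposed.f1 - baseline.f1:.3f}")
# The gap is driven by two effects: the baseline mis-assigns negated
# co-sentential distractors and abstains entirely on co-paragraph gold pairs.
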