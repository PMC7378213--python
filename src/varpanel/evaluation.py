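"""Benchmark scoring of predicted variant-disease pairs (precision/recall/F1).

Predictions and gold annotations are compared as sets of (doc_id, variant
canonical form, disease identifier) pairs; both sides must be normalized
with the same variant normalizer, and no credit is given for surface-form
matches.  The comparison is per-document by default with a corpus-global
option (pairs pooled across documents before set comparison).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .corpus_io import Document, Mention
from .association import assign_disease, baseline_assign
from .ner import normalize_variant

__all__ = ["GoldStandard", "PRF", "prf_from_counts", "f1_score",
           "evaluate_pairs", "compare_methods", "predict_pairs"]

Pair = tuple[str, str]  # (variant canonical, disease_id)


@dataclass
class GoldStandard:
    """Gold (variant, disease) pairs per document, canonical forms."""

    pairs: dict[str, set[Pair]] = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, path: str | Path, normalize: bool = True) -> "GoldStandard":
        """Read doc_id <tab> variant <tab> disease_id rows."""
        gold = cls()
        for ln, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{ln}: expected 3 columns")
            doc_id, variant, disease = parts
            canonical = normalize_variant(variant).canonical if normalize else variant
            gold.pairs.setdefault(doc_id, set()).add((canonical, disease))
        return gold


@dataclass(frozen=True)
class PRF:
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int
    degenerate: bool = False  # a zero-denominator convention was applied


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def prf_from_counts(tp: int, fp: int, fn: int) -> PRF:
    degenerate = (tp + fp == 0) or (tp + fn == 0)
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    return PRF(
        precision=precision,
        recall=recall,
        f1=f1_score(precision, recall),
        tp=tp, fp=fp, fn=fn,
        degenerate=degenerate,
    )


def evaluate_pairs(
    predicted: Mapping[str, set[Pair]],
    gold: GoldStandard,
    per_document: bool = True,
) -> PRF:
    """Set-based precision/recall/F1 at (doc_id, variant, disease) granularity.

    ``per_document=False`` pools pairs over documents first, so a pair
    found in a different document than annotated still counts.
    """
    if per_document:
        doc_ids = set(predicted) | set(gold.pairs)
        tp = fp = fn = 0
        for d in doc_ids:
            p = predicted.get(d, set())
            g = gold.pairs.get(d, set())
            tp += len(p & g)
            fp += len(p - g)
            fn += len(g - p)
    else:
        p = {pair for pairs in predicted.values() for pair in pairs}
        g = {pair for pairs in gold.pairs.values() for pair in pairs}
        tp, fp, fn = len(p & g), len(p - g), len(g - p)
    return prf_from_counts(tp, fp, fn)


def predict_pairs(
    docs: Sequence[Document],
    variant_mentions_by_doc: Mapping[str, Sequence[Mention]],
    disease_mentions_by_doc: Mapping[str, Sequence[Mention]],
    method: str = "proposed",
    aggregation: str = "max",
) -> dict[str, set[Pair]]:
    """Run a disease-assignment method over the corpus and collect pairs."""
    if method not in ("proposed", "baseline"):
        raise ValueError("method must be 'proposed' or 'baseline'")
    out: dict[str, set[Pair]] = {}
    for doc in docs:
        vms = list(variant_mentions_by_doc.get(doc.doc_id, ()))
        dms = list(disease_mentions_by_doc.get(doc.doc_id, ()))
        pairs: set[Pair] = set()
        for canonical in sorted({m.normalized_id for m in vms}):
            variant = normalize_variant(canonical)
            if method == "proposed":
                res = assign_disease(doc, variant, vms, dms, aggregation=aggregation)
            else:
                res = baseline_assign(doc, variant, vms, dms)
            if res.assigned_disease is not None:
                pairs.add((canonical, res.assigned_disease))
        if pairs:
            out[doc.doc_id] = pairs
    return out


def compare_methods(
    docs: Sequence[Document],
    variant_mentions_by_doc: Mapping[str, Sequence[Mention]],
    disease_mentions_by_doc: Mapping[str, Sequence[Mention]],
    gold: GoldStandard,
    per_document: bool = True,
) -> tuple[PRF, PRF]:
    """Score the composite method and the co-occurrence baseline side by side."""
    proposed = evaluate_pairs(
        predict_pairs(docs, variant_mentions_by_doc, disease_mentions_by_doc, "proposed"),
        gold, per_document=per_document,
    )
    baseline = evaluate_pairs(
        predict_pairs(docs, variant_mentions_by_doc, disease_mentions_by_doc, "baseline"),
        gold, per_document=per_document,
    )
    return proposed, baseline
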