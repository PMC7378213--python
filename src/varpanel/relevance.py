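"""Variant-relevance triage of articles by weighted keyword coverage.

Full-text mutation indexing is noisy: chemical formulae, figure labels and
similar "Character-Number-Character" strings masquerade as variants.  One
inexpensive defence is to restrict mining to articles whose full body reads
like a variant paper.  A weighted keyword list is learned from a sample of
articles known to mention at least one variant: each keyword's weight is its
relative document frequency in that sample.  An article is then kept when at
least a threshold fraction (default 10%, inclusive) of the keyword *types*
appear in its body text.

Coverage is unweighted presence — the fraction of distinct keywords found —
with the weights retained on the list for reporting and for the optional
weighted-coverage mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .corpus_io import Document, Section
from .resources import default_stopwords

__all__ = [
    "KeywordList",
    "RelevanceDecision",
    "build_keyword_list",
    "keyword_coverage",
    "is_variant_relevant",
]

DEFAULT_THRESHOLD = 0.10
DEFAULT_TOP_K = 500


def _is_numberish(token: str) -> bool:
    return bool(token) and not any(c.isalpha() for c in token)


def _doc_terms(doc: Document, section: Section | None = Section.BODY) -> set[str]:
    return {t.surface.lower() for t in doc.tokens_in(section)}


@dataclass(frozen=True)
class KeywordList:
    """Weighted variant-relevant keywords, highest weight first."""

    entries: tuple[tuple[str, float], ...]
    n_source_docs: int
    top_k: int
    min_df: int
    stopwords: frozenset[str] = field(repr=False, default_factory=frozenset)

    def __post_init__(self) -> None:
        terms = [t for t, _ in self.entries]
        if len(terms) != len(set(terms)):
            raise ValueError("keyword terms must be unique")
        weights = [w for _, w in self.entries]
        if any(a < b for a, b in zip(weights, weights[1:])):
            raise ValueError("weights must be non-increasing")
        if any(t in self.stopwords for t in terms):
            raise ValueError("stopwords may not appear in the keyword list")

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(t for t, _ in self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for term, weight in self.entries:
                fh.write(f"{term}\t{weight:.6g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KeywordList":
        entries: list[tuple[str, float]] = []
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if not line.strip():
                continue
            term, weight = line.split("\t")
            entries.append((term, float(weight)))
        return cls(
            entries=tuple(entries), n_source_docs=0, top_k=len(entries), min_df=0
        )


@dataclass(frozen=True)
class RelevanceDecision:
    doc_id: str
    coverage: float
    threshold: float
    relevant: bool

    def __post_init__(self) -> None:
        assert self.relevant == (self.coverage >= self.threshold)


def build_keyword_list(
    variant_positive_docs: Sequence[Document],
    stopwords: Iterable[str] | None = None,
    top_k: int = DEFAULT_TOP_K,
    min_df: int | None = None,
) -> KeywordList:
    """Learn the weighted keyword list from variant-positive articles.

    Every input document is assumed to mention at least one variant (the
    caller samples them, e.g. via the variant recognizer).  A term's weight
    is the fraction of source documents whose body contains it.  Stopwords,
    pure-number tokens and terms below ``min_df`` document frequency are
    dropped; the ``top_k`` heaviest terms are kept, ties broken
    lexicographically.

    ``min_df`` defaults to 5% of the number of source documents (at least 1).
    """
    if not variant_positive_docs:
        raise ValueError("cannot build a keyword list from an empty document list")
    if top_k <= 0:
        raise ValueError("top_k must be positive")
    stop = frozenset(w.lower() for w in stopwords) if stopwords is not None else default_stopwords()
    n = len(variant_positive_docs)
    if min_df is None:
        min_df = max(1, math.ceil(0.05 * n))

    df: dict[str, int] = {}
    for doc in variant_positive_docs:
        for term in _doc_terms(doc):
            df[term] = df.get(term, 0) + 1

    candidates = [
        (term, count)
        for term, count in df.items()
        if count >= min_df and term not in stop and not _is_numberish(term)
    ]
    candidates.sort(key=lambda tc: (-tc[1], tc[0]))
    entries = tuple((term, count / n) for term, count in candidates[:top_k])
    return KeywordList(
        entries=entries, n_source_docs=n, top_k=top_k, min_df=min_df, stopwords=stop
    )


def keyword_coverage(
    doc: Document, keywords: KeywordList, weighted: bool = False
) -> float:
    """Fraction of keyword types present in the document's body tokens.

    With ``weighted=True`` the present keywords' weights are summed and
    divided by the total weight instead.
    """
    if len(keywords) == 0:
        raise ValueError("keyword list is empty")
    present = _doc_terms(doc)
    if weighted:
        total = sum(w for _, w in keywords.entries)
        hit = sum(w for t, w in keywords.entries if t in present)
        return hit / total if total > 0 else 0.0
    return sum(1 for t in keywords.terms if t in present) / len(keywords)


def is_variant_relevant(
    doc: Document,
    keywords: KeywordList,
    threshold: float = DEFAULT_THRESHOLD,
    weighted: bool = False,
) -> RelevanceDecision:
    """Decide variant relevance: coverage >= threshold (inclusive)."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    cov = keyword_coverage(doc, keywords, weighted=weighted)
    return RelevanceDecision(
        doc_id=doc.doc_id, coverage=cov, threshold=threshold, relevant=cov >= threshold
    )
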