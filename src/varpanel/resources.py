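"""Packaged default resources: stopwords, sentiment lexicon, synthesis vocab."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources


def _read_text(name: str) -> str:
    return (resources.files("varpanel") / "data" / name).read_text(encoding="utf-8")


@lru_cache(maxsize=None)
def default_stopwords() -> frozenset[str]:
    return frozenset(
        w.strip().lower() for w in _read_text("stopwords.txt").splitlines() if w.strip()
    )


@lru_cache(maxsize=None)
def default_sentiment_lexicon() -> dict[str, float]:
    lex: dict[str, float] = {}
    for line in _read_text("sentiment_lexicon.tsv").splitlines():
        if not line.strip():
            continue
        term, valence = line.split("\t")
        lex[term.strip().lower()] = float(valence)
    return lex


def _read_lexicon(name: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in _read_text(name).splitlines():
        if not line.strip():
            continue
        term, ident = line.split("\t")
        out[term.strip()] = ident.strip()
    return out


@lru_cache(maxsize=None)
def default_gene_lexicon() -> dict[str, str]:
    """Gene symbol -> canonical symbol (small packaged fixture)."""
    return _read_lexicon("genes.tsv")


@lru_cache(maxsize=None)
def default_disease_lexicon() -> dict[str, str]:
    """Disease name -> identifier (small packaged fixture)."""
    return _read_lexicon("diseases.tsv")


@lru_cache(maxsize=None)
def topical_vocabulary() -> tuple[str, ...]:
    """Variant-domain vocabulary used by the corpus generator."""
    return tuple(
        w.strip() for w in _read_text("topical_words.txt").splitlines() if w.strip()
    )


@lru_cache(maxsize=None)
def background_vocabulary() -> tuple[str, ...]:
    """Off-topic vocabulary for background articles."""
    return tuple(
        w.strip() for w in _read_text("background_words.txt").splitlines() if w.strip()
    )
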