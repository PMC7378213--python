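"""Synthetic corpora and expression cohorts with known ground truth.

The corpus generator emulates the structure the extraction pipeline
assumes in real full-text articles, at a desk scale where every stage can
be verified against planted truth:

* variant-positive articles share a topical vocabulary (so a
  keyword-coverage relevance filter is learnable), plant one variant per
  article in a mix of surface formats (one-letter / three-letter / HGVS
  protein, HGVS nucleotide, rsID) with a gene mention in the same sentence
  and the gold disease mention at a configured distance (same sentence,
  same paragraph, or a distant paragraph);
* distractor diseases occupy distant paragraphs; at a configurable rate a
  distractor co-occurs with an extra variant occurrence in an explicitly
  negated sentence, the situation where plain sentence co-occurrence
  counting is misled but the polarity-aware score is not;
* "Character-Number-Character" decoys (figure/table labels) are inserted
  next to their cue words at a configured rate;
* background articles draw from an unrelated vocabulary, mention no
  variants, and carry only a small topical leakage.

The expression generator plants an additive class shift on panel genes on
top of per-gene baselines shared across cohorts, plus Gaussian noise, so
cross-cohort classification has a transferable signal of known size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus_io import Document, parse_document
from .ner import AA3_TO_1, CoordinateRecord, normalize_variant
from .resources import (
    background_vocabulary,
    default_disease_lexicon,
    default_gene_lexicon,
    topical_vocabulary,
)
from .validation import DISEASE, HEALTHY, ExpressionDataset

__all__ = ["CorpusConfig", "GroundTruth", "generate_corpus", "generate_expression",
           "default_expression_genes", "write_corpus_jsonl"]

_AA1_TO_3 = {v: k for k, v in AA3_TO_1.items() if k not in ("Ter", "Stop")}
_SURFACE_FORMATS = ("protein1", "protein3", "hgvs_p", "hgvs_c", "rsid")


@dataclass(frozen=True)
class CorpusConfig:
    """Study conditions for a generated corpus."""

    n_variant_docs: int = 200
    n_background_docs: int = 200
    variants_per_doc: int = 1
    # probability of each variant surface format, order as _SURFACE_FORMATS
    format_mix: tuple[float, ...] = (0.3, 0.2, 0.2, 0.15, 0.15)
    # gold disease placement: same sentence / same paragraph / distant paragraph
    distance_distribution: tuple[float, float, float] = (0.6, 0.3, 0.1)
    n_distractor_diseases: int = 2
    # chance a distractor gets a negated co-sentence with an extra variant occurrence
    distractor_cosentence_rate: float = 0.3
    # chance the gold association sentence carries positive sentiment phrasing
    sentiment_phrase_rate: float = 0.8
    # expected number of figure/table decoy sentences per variant document
    decoy_rate: float = 1.0
    # fraction of background-document tokens leaked from the topical vocabulary
    background_topical_leakage: float = 0.05

    def __post_init__(self) -> None:
        if self.n_variant_docs < 0 or self.n_background_docs < 0:
            raise ValueError("document counts must be >= 0")
        if self.variants_per_doc < 1:
            raise ValueError("variants_per_doc must be >= 1")
        for name, probs in (("format_mix", self.format_mix),
                            ("distance_distribution", self.distance_distribution)):
            if abs(sum(probs) - 1.0) > 1e-9 or any(p < 0 for p in probs):
                raise ValueError(f"{name} must be a probability vector summing to 1")


@dataclass
class GroundTruth:
    """Planted truth for a generated corpus."""

    # doc_id -> set of (variant canonical, gene symbol, disease_id)
    triplets: dict[str, set[tuple[str, str, str]]] = field(default_factory=dict)
    relevance: dict[str, bool] = field(default_factory=dict)
    # doc_id -> [(surface, char_start, char_end)] for every planted entity mention
    mention_offsets: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    resolver: dict[tuple[str, str], CoordinateRecord] = field(default_factory=dict)

    def gold_pairs(self) -> dict[str, set[tuple[str, str]]]:
        return {
            d: {(v, dis) for v, _, dis in trips}
            for d, trips in self.triplets.items()
            if trips
        }


def _sentence(rng: np.random.Generator, vocab: Sequence[str], n_words: int) -> str:
    words = [str(vocab[i]) for i in rng.integers(0, len(vocab), n_words)]
    return words[0].capitalize() + " " + " ".join(words[1:]) + "."


def _filler_paragraph(rng: np.random.Generator, vocab: Sequence[str]) -> str:
    return " ".join(
        _sentence(rng, vocab, int(rng.integers(8, 15)))
        for _ in range(int(rng.integers(2, 5)))
    )


def _make_surface(rng: np.random.Generator, fmt: str, uid: int) -> tuple[str, str]:
    """Return (surface as written, canonical form)."""
    aa = sorted(_AA1_TO_3)
    ref, alt = rng.choice(aa, size=2, replace=False)
    pos = 50 + uid
    if fmt == "protein1":
        surface = f"{ref}{pos}{alt}"
    elif fmt == "protein3":
        surface = f"{_AA1_TO_3[ref]}{pos}{_AA1_TO_3[alt]}"
    elif fmt == "hgvs_p":
        surface = f"p.{_AA1_TO_3[ref]}{pos}{_AA1_TO_3[alt]}"
    elif fmt == "hgvs_c":
        nref, nalt = rng.choice(list("ACGT"), size=2, replace=False)
        surface = f"c.{pos}{nref}>{nalt}"
    elif fmt == "rsid":
        surface = f"rs{10000 + uid}"
    else:
        raise ValueError(f"unknown surface format {fmt!r}")
    return surface, normalize_variant(surface).canonical


_DECOYS = (
    "As shown in Figure S{n}{letter} the measured expression pattern was stable.",
    "Table S{n}{letter} lists the baseline characteristics of the cohort.",
    "The chromatogram in panel S{n}{letter} was obtained under identical conditions.",
)


def generate_corpus(
    config: CorpusConfig, seed: int
) -> tuple[list[Document], GroundTruth]:
    """Generate a corpus with planted associations; byte-deterministic in
    (config, seed)."""
    rng = np.random.default_rng(seed)
    topical = topical_vocabulary()
    background = background_vocabulary()
    genes = list(default_gene_lexicon())
    diseases = default_disease_lexicon()
    disease_names = list(diseases)

    docs: list[Document] = []
    truth = GroundTruth()
    uid = 0

    for i in range(config.n_variant_docs):
        doc_id = f"VD{i:05d}"
        planted: list[str] = []  # surfaces to locate afterwards
        triplets: set[tuple[str, str, str]] = set()
        paragraphs: list[str] = []

        for _ in range(config.variants_per_doc):
            uid += 1
            fmt = _SURFACE_FORMATS[
                rng.choice(len(_SURFACE_FORMATS), p=config.format_mix)
            ]
            surface, canonical = _make_surface(rng, fmt, uid)
            gene = str(rng.choice(genes))
            gold_name = str(rng.choice(disease_names))
            gold_id = diseases[gold_name]
            distractor_names = [
                str(d)
                for d in rng.choice(
                    [d for d in disease_names if d != gold_name],
                    size=min(config.n_distractor_diseases, len(disease_names) - 1),
                    replace=False,
                )
            ]

            # distractor paragraphs come first, so a misled co-occurrence
            # counter also loses the earlier-first-mention tie-break; each is
            # padded with a trailing filler sentence so the distractor disease
            # never outranks the gold disease in raw token distance
            for dn in distractor_names:
                if rng.random() < config.distractor_cosentence_rate:
                    paragraphs.append(
                        f"{_sentence(rng, topical, 8)} "
                        f"The {surface} allele was not associated with {dn} "
                        f"in this cohort. {_sentence(rng, topical, 10)}"
                    )
                    planted.extend([surface, dn])
                else:
                    paragraphs.append(
                        f"Patients with {dn} were recruited separately. "
                        f"{_sentence(rng, topical, 10)}"
                    )
                    planted.append(dn)

            # a filler paragraph separates the distractor block from the gold
            # association, keeping the gold disease the closest one by token
            # distance for the gold occurrence
            if distractor_names:
                paragraphs.append(_filler_paragraph(rng, topical))

            placement = ("co_sentence", "co_paragraph", "distant")[
                rng.choice(3, p=config.distance_distribution)
            ]
            if rng.random() < config.sentiment_phrase_rate:
                link_text = "was significantly associated with increased risk of"
            else:
                link_text = "was examined in patients with"
            if placement == "co_sentence":
                paragraphs.append(
                    f"{_sentence(rng, topical, 9)} "
                    f"The {surface} substitution in {gene} {link_text} {gold_name}."
                )
            elif placement == "co_paragraph":
                paragraphs.append(
                    f"The {surface} substitution in {gene} was analyzed. "
                    f"This substitution {link_text} {gold_name}."
                )
            else:  # distant: gold disease in the following paragraph
                paragraphs.append(
                    f"The {surface} substitution in {gene} was analyzed. "
                    f"{_sentence(rng, topical, 9)}"
                )
                paragraphs.append(
                    f"The cohort comprised individuals diagnosed with {gold_name}. "
                    f"{_sentence(rng, topical, 9)}"
                )
            planted.extend([surface, gene, gold_name])
            triplets.add((canonical, gene, gold_id))

            if (gene, canonical) not in truth.resolver:
                nref, nalt = rng.choice(list("ACGT"), size=2, replace=False)
                truth.resolver[(gene, canonical)] = CoordinateRecord(
                    chrom=str(1 + uid % 22),
                    pos=int(1000 + uid),
                    ref=str(nref),
                    alt=str(nalt),
                )

        # topical filler only at the edges, so it never perturbs the
        # distance structure planted above
        for _ in range(int(rng.integers(1, 3))):
            paragraphs.insert(0, _filler_paragraph(rng, topical))
        for _ in range(int(rng.integers(1, 3))):
            paragraphs.append(_filler_paragraph(rng, topical))
        for _ in range(rng.poisson(config.decoy_rate)):
            template = _DECOYS[rng.choice(len(_DECOYS))]
            decoy = template.format(
                n=int(rng.integers(1, 6)), letter=str(rng.choice(list("ABCDE")))
            )
            paragraphs.append(decoy)

        raw = {
            "doc_id": doc_id,
            "title": _sentence(rng, topical, 7).rstrip("."),
            "abstract": _filler_paragraph(rng, topical),
            "body": "\n\n".join(paragraphs),
        }
        doc = parse_document(raw)
        docs.append(doc)
        truth.triplets[doc_id] = triplets
        truth.relevance[doc_id] = True
        truth.mention_offsets[doc_id] = _locate_planted(doc, planted)

    leak = config.background_topical_leakage
    for i in range(config.n_background_docs):
        doc_id = f"BG{i:05d}"
        vocab = list(background)
        n_leak = int(round(leak * len(vocab)))
        if n_leak:
            vocab = vocab + [str(w) for w in rng.choice(topical, size=n_leak)]
        body = "\n\n".join(
            _filler_paragraph(rng, vocab) for _ in range(int(rng.integers(4, 8)))
        )
        raw = {
            "doc_id": doc_id,
            "title": _sentence(rng, vocab, 7).rstrip("."),
            "abstract": _filler_paragraph(rng, vocab),
            "body": body,
        }
        docs.append(parse_document(raw))
        truth.triplets[doc_id] = set()
        truth.relevance[doc_id] = False

    return docs, truth


def _locate_planted(doc: Document, surfaces: list[str]) -> list[tuple[str, int, int]]:
    """Record an offset for each planted surface; every surface must exist."""
    out: list[tuple[str, int, int]] = []
    for s in surfaces:
        start = doc.full_text.find(s)
        if start < 0:
            raise AssertionError(f"planted surface {s!r} missing from {doc.doc_id}")
        out.append((s, start, start + len(s)))
    return out


def write_corpus_jsonl(docs: Sequence[Document], path: str | Path) -> None:
    import json

    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            body = "\n\n".join(
                doc.full_text[p.char_start : p.char_end] for p in doc.body_paragraphs
            )
            fh.write(
                json.dumps(
                    {
                        "doc_id": doc.doc_id,
                        "title": doc.title,
                        "abstract": doc.abstract,
                        "body": body,
                    }
                )
                + "\n"
            )


def default_expression_genes(n_background: int = 150) -> list[str]:
    """Packaged gene symbols plus synthetic filler genes."""
    return list(default_gene_lexicon()) + [f"BG{i:04d}" for i in range(n_background)]


def generate_expression(
    n_datasets: int = 3,
    genes: Sequence[str] | None = None,
    panel_genes: Sequence[str] | None = None,
    effect_size: float = 3.0,
    n_per_class: int = 30,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> list[ExpressionDataset]:
    """Generate expression cohorts with an additive class shift on panel genes.

    Per-gene baselines (uniform on [1, 2]) are shared across cohorts so the
    planted signal transfers between them; DISEASE samples of panel genes
    are shifted by ``effect_size`` and all values get Gaussian noise of
    ``noise_sd``.  Deterministic given ``seed``.
    """
    if genes is None:
        genes = default_expression_genes()
    if panel_genes is None:
        panel_genes = list(default_gene_lexicon())[:20]
    genes = list(genes)
    panel_genes = list(panel_genes)
    if not set(panel_genes) <= set(genes):
        raise ValueError("panel_genes must be a subset of genes")
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2")
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")

    rng = np.random.default_rng(seed)
    baseline = rng.uniform(1.0, 2.0, size=len(genes))
    panel_mask = np.array([g in set(panel_genes) for g in genes])

    datasets: list[ExpressionDataset] = []
    for d in range(n_datasets):
        ds_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        n = 2 * n_per_class
        labels = np.array([HEALTHY] * n_per_class + [DISEASE] * n_per_class)
        values = np.tile(baseline[:, None], (1, n))
        values[np.ix_(panel_mask, labels == DISEASE)] += effect_size
        values += ds_rng.normal(0.0, noise_sd, size=values.shape)
        samples = [f"DS{d}_S{j:03d}" for j in range(n)]
        datasets.append(
            ExpressionDataset(
                dataset_id=f"DS{d}",
                values=pd.DataFrame(values, index=genes, columns=samples),
                labels=pd.Series(labels, index=samples),
            )
        )
    return datasets
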