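"""Variant-gene and variant-disease association extraction.

Within one article each variant mention is linked to its nearest gene
mention (same sentence preferred, then same paragraph, then anywhere in the
document), and each (gene, variant) pair is checked against a genomic
coordinate resolver — pairs with no resolvable coordinates are treated as
recognizer false positives and excluded from panel construction.

Variant-disease linking follows a proximity-plus-polarity score.  For a
variant V mentioned k times in an article, the candidate collection is
C = {V, D1..Dk}: each of the k occurrences paired with its closest disease
mention by token count.  Each candidate is scored as

    total = SSO + SPO + SS

where SSO (same-sentence occurrence) and SPO (same-paragraph occurrence)
are binary, and SS is the lexicon-based sentiment polarity of the text
strictly between the two mentions, in [-1, 1].  SSO = 1 implies SPO = 1, so
total lies in [-1, 3].  The variant is assigned the disease whose best
candidate score is highest (per-disease aggregation across occurrences is
the maximum by default; sum is available).  A plain sentence co-occurrence
counter serves as the baseline comparator.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .corpus_io import Document, Location, Mention
from .ner import CoordinateRecord, VariantKey, normalize_variant
from .resources import default_sentiment_lexicon

__all__ = [
    "PairStatus",
    "VariantGenePair",
    "LinkResult",
    "DiseaseCandidate",
    "AssociationResult",
    "token_distance",
    "link_variant_gene",
    "load_resolver_table",
    "resolve_coordinates",
    "collect_closest_diseases",
    "score_candidate",
    "sentiment_polarity",
    "assign_disease",
    "baseline_assign",
    "NEGATORS",
]

NEGATORS = frozenset({"not", "no", "never", "without"})
_WORD_RE = re.compile(r"[A-Za-z0-9](?:[A-Za-z0-9._>\-/+*']*[A-Za-z0-9>])?")


class PairStatus(str, Enum):
    RESOLVED = "RESOLVED"
    UNRESOLVED = "UNRESOLVED"


@dataclass(frozen=True)
class VariantGenePair:
    variant: VariantKey
    gene: str
    doc_id: str
    variant_location: Location
    gene_location: Location
    coordinates: CoordinateRecord | None = None
    status: PairStatus = PairStatus.UNRESOLVED

    def __post_init__(self) -> None:
        assert (self.status is PairStatus.RESOLVED) == (self.coordinates is not None)


@dataclass
class LinkResult:
    pairs: list[VariantGenePair]
    unpaired: list[Mention]  # variant mentions with no gene in the document


@dataclass(frozen=True)
class DiseaseCandidate:
    """One (variant occurrence, closest disease) pair and its score parts."""

    variant: VariantKey
    occurrence_index: int  # 1-based within the document
    disease_id: str
    distance_tokens: int
    occurrence_location: Location
    disease_location: Location
    sso: int = 0
    spo: int = 0
    ss: float = 0.0
    total: float = 0.0

    def __post_init__(self) -> None:
        assert self.distance_tokens >= 0
        assert self.total == self.sso + self.spo + self.ss
        assert not (self.sso == 1 and self.spo == 0), "same sentence implies same paragraph"


@dataclass
class AssociationResult:
    variant: VariantKey
    assigned_disease: str | None
    winning_candidate: DiseaseCandidate | None
    k: int
    all_candidates: list[DiseaseCandidate] = field(default_factory=list)
    score: float | None = None


def token_distance(a: Location, b: Location) -> int:
    """Tokens strictly between two spans; 0 when adjacent or overlapping."""
    if a.token_end <= b.token_start:
        return b.token_start - a.token_end
    if b.token_end <= a.token_start:
        return a.token_start - b.token_end
    return 0


def _same_sentence(a: Location, b: Location) -> bool:
    return (a.paragraph_index, a.sentence_index) == (b.paragraph_index, b.sentence_index)


def _same_paragraph(a: Location, b: Location) -> bool:
    return a.paragraph_index == b.paragraph_index


def link_variant_gene(
    doc: Document,
    variant_mentions: Sequence[Mention],
    gene_mentions: Sequence[Mention],
) -> LinkResult:
    """Pair every variant mention with its nearest gene mention.

    Proximity tiers: same sentence beats same paragraph beats same document,
    regardless of raw distance; within a tier the smallest token distance
    wins, ties broken by the gene preceding the variant, then by smaller
    character offset.  Variants with no gene mention anywhere are reported
    unpaired.
    """
    result = LinkResult(pairs=[], unpaired=[])
    for vm in variant_mentions:
        if not gene_mentions:
            result.unpaired.append(vm)
            continue

        def sort_key(gm: Mention) -> tuple:
            if _same_sentence(vm.location, gm.location):
                tier = 0
            elif _same_paragraph(vm.location, gm.location):
                tier = 1
            else:
                tier = 2
            dist = token_distance(vm.location, gm.location)
            precedes = 0 if gm.location.char_start < vm.location.char_start else 1
            return (tier, dist, precedes, gm.location.char_start)

        best = min(gene_mentions, key=sort_key)
        result.pairs.append(
            VariantGenePair(
                variant=normalize_variant(vm.surface),
                gene=best.normalized_id.upper(),
                doc_id=doc.doc_id,
                variant_location=vm.location,
                gene_location=best.location,
            )
        )
    return result


def load_resolver_table(
    path: str | Path,
) -> dict[tuple[str, str], CoordinateRecord]:
    """Load the (gene, canonical variant) -> genomic coordinates table.

    Tab-separated columns: gene, variant_canonical, chrom, pos, ref, alt.
    """
    table: dict[tuple[str, str], CoordinateRecord] = {}
    for ln, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 6:
            raise ValueError(f"{path}:{ln}: expected 6 columns, got {len(parts)}: {line!r}")
        gene, canonical, chrom, pos_s, ref, alt = parts
        try:
            rec = CoordinateRecord(chrom=chrom, pos=int(pos_s), ref=ref, alt=alt)
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: malformed coordinate row: {exc}") from exc
        table[(gene.upper(), canonical)] = rec
    return table


def resolve_coordinates(
    pairs: Iterable[VariantGenePair],
    resolver: Mapping[tuple[str, str], CoordinateRecord],
) -> list[VariantGenePair]:
    """Attach genomic coordinates; pairs without a match stay UNRESOLVED.

    Unresolved pairs are the pipeline's false-positive sink: they are kept
    for reporting but never reach panel construction.
    """
    out: list[VariantGenePair] = []
    for pair in pairs:
        rec = resolver.get((pair.gene, pair.variant.canonical))
        if rec is not None:
            out.append(replace(pair, coordinates=rec, status=PairStatus.RESOLVED))
        else:
            out.append(replace(pair, coordinates=None, status=PairStatus.UNRESOLVED))
    return out


def collect_closest_diseases(
    doc: Document,
    variant: VariantKey,
    variant_mentions: Sequence[Mention],
    disease_mentions: Sequence[Mention],
) -> list[DiseaseCandidate]:
    """Build C = {V, D1..Dk}: per occurrence, the closest disease mention.

    k is the number of occurrences of the variant's canonical key in the
    document.  Closeness is token distance (strictly-between count); ties go
    to the preceding mention, then the smaller character offset.  With no
    disease mentions the collection is empty.
    """
    occurrences = sorted(
        (m for m in variant_mentions if m.normalized_id == variant.canonical),
        key=lambda m: m.location.char_start,
    )
    if not disease_mentions:
        return []
    candidates: list[DiseaseCandidate] = []
    for idx, occ in enumerate(occurrences, start=1):

        def sort_key(dm: Mention) -> tuple:
            dist = token_distance(occ.location, dm.location)
            precedes = 0 if dm.location.char_start < occ.location.char_start else 1
            return (dist, precedes, dm.location.char_start)

        best = min(disease_mentions, key=sort_key)
        candidates.append(
            DiseaseCandidate(
                variant=variant,
                occurrence_index=idx,
                disease_id=best.normalized_id,
                distance_tokens=token_distance(occ.location, best.location),
                occurrence_location=occ.location,
                disease_location=best.location,
            )
        )
    return candidates


def sentiment_polarity(
    text: str,
    lexicon: Mapping[str, float] | None = None,
    negators: frozenset[str] = NEGATORS,
) -> float:
    """Lexicon polarity of a text span, in [-1, 1].

    The mean valence of lexicon-matched tokens, with a token's valence
    sign-flipped when a negator occurs within the three preceding tokens.
    Text with no lexicon hit scores 0.
    """
    if lexicon is None:
        lexicon = default_sentiment_lexicon()
    tokens = [m.group(0).lower() for m in _WORD_RE.finditer(text)]
    valences: list[float] = []
    for i, tok in enumerate(tokens):
        if tok not in lexicon:
            continue
        v = lexicon[tok]
        if any(t in negators for t in tokens[max(0, i - 3) : i]):
            v = -v
        valences.append(v)
    if not valences:
        return 0.0
    mean = sum(valences) / len(valences)
    return max(-1.0, min(1.0, mean))


def score_candidate(
    doc: Document,
    candidate: DiseaseCandidate,
    lexicon: Mapping[str, float] | None = None,
) -> DiseaseCandidate:
    """Fill SSO, SPO, SS and the total for one candidate.

    SS is computed on the text strictly between the two mention spans in
    document order; the mention tokens themselves are excluded, and text
    after both mentions never affects the score.
    """
    a, b = candidate.occurrence_location, candidate.disease_location
    sso = 1 if _same_sentence(a, b) else 0
    spo = 1 if _same_paragraph(a, b) else 0
    lo, hi = (a, b) if a.char_start <= b.char_start else (b, a)
    between = doc.full_text[lo.char_end : hi.char_start] if lo.char_end < hi.char_start else ""
    ss = sentiment_polarity(between, lexicon=lexicon)
    return replace(candidate, sso=sso, spo=spo, ss=ss, total=sso + spo + ss)


def _pick_winner(
    per_disease: dict[str, list[DiseaseCandidate]],
    scores: dict[str, float],
) -> str:
    """Argmax disease with ties broken by more supporting occurrences,
    then earlier first mention, then identifier."""

    def key(d: str) -> tuple:
        cands = per_disease[d]
        first_char = min(c.disease_location.char_start for c in cands)
        return (-scores[d], -len(cands), first_char, d)

    return min(per_disease, key=key)


def assign_disease(
    doc: Document,
    variant: VariantKey,
    variant_mentions: Sequence[Mention],
    disease_mentions: Sequence[Mention],
    aggregation: str = "max",
    lexicon: Mapping[str, float] | None = None,
) -> AssociationResult:
    """Assign the variant its best-supported disease by the composite score.

    Candidates are collected (closest disease per occurrence), scored, and
    grouped by disease; a disease's score aggregates its per-occurrence
    totals (maximum by default, sum optional).  The highest-scoring disease
    wins.  With zero occurrences or no disease mentions nothing is assigned.
    """
    if aggregation not in ("max", "sum"):
        raise ValueError("aggregation must be 'max' or 'sum'")
    candidates = [
        score_candidate(doc, c, lexicon=lexicon)
        for c in collect_closest_diseases(doc, variant, variant_mentions, disease_mentions)
    ]
    k = len({m.location.char_start for m in variant_mentions
             if m.normalized_id == variant.canonical})
    if not candidates:
        return AssociationResult(variant=variant, assigned_disease=None,
                                 winning_candidate=None, k=k)
    per_disease: dict[str, list[DiseaseCandidate]] = {}
    for c in candidates:
        per_disease.setdefault(c.disease_id, []).append(c)
    agg = max if aggregation == "max" else sum
    scores = {d: agg(c.total for c in cs) for d, cs in per_disease.items()}
    winner = _pick_winner(per_disease, scores)
    winning = max(per_disease[winner], key=lambda c: c.total)
    return AssociationResult(
        variant=variant,
        assigned_disease=winner,
        winning_candidate=winning,
        k=k,
        all_candidates=candidates,
        score=scores[winner],
    )


def baseline_assign(
    doc: Document,
    variant: VariantKey,
    variant_mentions: Sequence[Mention],
    disease_mentions: Sequence[Mention],
) -> AssociationResult:
    """Sentence co-occurrence baseline.

    A disease's score is the number of sentences containing both the
    variant and that disease; the argmax is assigned with the same
    tie-breaks as the composite method.  Without any co-sentential disease
    nothing is assigned (the baseline has no proximity fallback).
    """
    occurrences = [m for m in variant_mentions if m.normalized_id == variant.canonical]
    k = len({m.location.char_start for m in occurrences})
    counts: dict[str, set[tuple[int, int]]] = {}
    supporters: dict[str, list[DiseaseCandidate]] = {}
    for dm in disease_mentions:
        for occ in occurrences:
            if _same_sentence(occ.location, dm.location):
                sent = (dm.location.paragraph_index, dm.location.sentence_index)
                counts.setdefault(dm.normalized_id, set()).add(sent)
                supporters.setdefault(dm.normalized_id, []).append(
                    DiseaseCandidate(
                        variant=variant,
                        occurrence_index=1,
                        disease_id=dm.normalized_id,
                        distance_tokens=token_distance(occ.location, dm.location),
                        occurrence_location=occ.location,
                        disease_location=dm.location,
                        sso=1, spo=1, ss=0.0, total=2.0,
                    )
                )
    if not counts:
        return AssociationResult(variant=variant, assigned_disease=None,
                                 winning_candidate=None, k=k)
    scores = {d: float(len(sents)) for d, sents in counts.items()}
    winner = _pick_winner(supporters, scores)
    return AssociationResult(
        variant=variant,
        assigned_disease=winner,
        winning_candidate=supporters[winner][0],
        k=k,
        all_candidates=[c for cs in supporters.values() for c in cs],
        score=scores[winner],
    )
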