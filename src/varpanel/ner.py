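"""Built-in entity recognizers: variants by pattern, genes/diseases by lexicon.

These are deliberately lightweight stand-ins for the dedicated recognizers
used in large-scale literature mining (tmVar-class variant taggers,
GNormPlus-class gene normalizers, DNorm-class disease normalizers).  When
external standoff annotations are supplied they take precedence; the
built-ins let the pipeline run end-to-end on its own.

Variant surfaces covered:

* HGVS protein substitutions: ``p.Ala123Val``, ``p.A123V``
* bare protein substitutions: ``Ala123Val``, ``A123V``
* HGVS nucleotide substitutions and deletions: ``c.123A>G``, ``g.456del``
* dbSNP identifiers: ``rs12345``

Bare one-letter substitutions share the "Character-Number-Character" shape
with figure panels, compound names and similar strings, the classic
false-positive source in full-text mining.  Two guards apply: both letters
must be valid amino-acid codes with reference != alternate, and matches
adjacent to figure/table/chemical cue words are suppressed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum

from .corpus_io import Document, EntityClass, Mention, MentionSource

__all__ = [
    "VariantKind",
    "VariantKey",
    "CoordinateRecord",
    "find_variant_mentions",
    "normalize_variant",
    "dictionary_match",
    "AA3_TO_1",
]

# standard 20 amino acids plus Ter/stop
AA3_TO_1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": "X", "Stop": "X",
}
_AA1 = set("ARNDCQEGHILKMFPSTWYVX")

_CUE_WORDS = frozenset(
    {
        "figure", "figures", "fig", "figs", "table", "tables", "panel",
        "panels", "supplementary", "appendix", "compound", "compounds",
        "chemical", "buffer", "solution", "lane", "lanes", "well", "wells",
    }
)

_AA3_ALT = "|".join(AA3_TO_1)
_P_PROT3 = re.compile(rf"(?:p\.)?({_AA3_ALT})(\d+)({_AA3_ALT})$")
_P_PROT1 = re.compile(r"(?:p\.)?([A-Z])(\d+)([A-Z])$")
_P_NT_SUB = re.compile(r"([cgmn])\.(\d+)([ACGTacgt])>([ACGTacgt])$", re.IGNORECASE)
_P_NT_DEL = re.compile(
    r"([cgmn])\.(\d+)(?:_(\d+))?(del|dup|ins)([ACGTacgt]*)$", re.IGNORECASE
)
_P_RSID = re.compile(r"[Rr][Ss](\d+)$")


class VariantKind(str, Enum):
    PROTEIN_SUB = "PROTEIN_SUB"
    DNA_SUB = "DNA_SUB"
    RSID = "RSID"
    OTHER = "OTHER"


@dataclass(frozen=True)
class VariantKey:
    """Canonical, surface-independent identity of a variant mention."""

    canonical: str
    kind: VariantKind
    rsid: str | None = None

    def __post_init__(self) -> None:
        if not self.canonical:
            raise ValueError("canonical form must be non-empty")


@dataclass(frozen=True)
class CoordinateRecord:
    """Genomic coordinates: chromosome, 1-based position, ref/alt alleles."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")


def normalize_variant(surface: str) -> VariantKey:
    """Map a matched variant surface to its canonical key.

    Protein substitutions collapse onto one-letter notation with a ``p.``
    prefix ("Ala123Val", "A123V" and "p.Ala123Val" all become "p.A123V");
    nucleotide forms get a lowercase prefix and uppercase alleles; rsIDs are
    lowercased.  Idempotent: normalizing a canonical form returns it
    unchanged.
    """
    s = surface.strip()
    m = _P_RSID.match(s)
    if m:
        return VariantKey(canonical=f"rs{m.group(1)}", kind=VariantKind.RSID,
                          rsid=f"rs{m.group(1)}")
    m = _P_PROT3.match(s)
    if m:
        ref3, pos, alt3 = m.groups()
        ref, alt = AA3_TO_1[ref3], AA3_TO_1[alt3]
        _check_protein_sub(ref, int(pos), alt)
        return VariantKey(canonical=f"p.{ref}{int(pos)}{alt}", kind=VariantKind.PROTEIN_SUB)
    m = _P_PROT1.match(s)
    if m:
        ref, pos, alt = m.groups()
        for code in (ref, alt):
            if code not in _AA1:
                raise ValueError(f"unknown amino-acid code {code!r} in {surface!r}")
        _check_protein_sub(ref, int(pos), alt)
        return VariantKey(canonical=f"p.{ref}{int(pos)}{alt}", kind=VariantKind.PROTEIN_SUB)
    m = _P_NT_SUB.match(s)
    if m:
        prefix, pos, ref, alt = m.groups()
        return VariantKey(
            canonical=f"{prefix.lower()}.{int(pos)}{ref.upper()}>{alt.upper()}",
            kind=VariantKind.DNA_SUB,
        )
    m = _P_NT_DEL.match(s)
    if m:
        prefix, p1, p2, op, seq = m.groups()
        span = f"{int(p1)}_{int(p2)}" if p2 else f"{int(p1)}"
        return VariantKey(
            canonical=f"{prefix.lower()}.{span}{op.lower()}{seq.upper()}",
            kind=VariantKind.OTHER,
        )
    raise ValueError(f"surface {surface!r} does not match any variant pattern")


def _check_protein_sub(ref: str, pos: int, alt: str) -> None:
    if pos < 1:
        raise ValueError(f"protein position must be positive, got {pos}")
    if ref == alt:
        raise ValueError(f"reference and alternate residues are identical ({ref})")


def _token_is_variant(surface: str) -> bool:
    try:
        normalize_variant(surface)
    except ValueError:
        return False
    return True


def find_variant_mentions(doc: Document) -> list[Mention]:
    """Scan the document's tokens for variant surfaces.

    Matching is token-aligned, so patterns embedded in longer alphanumeric
    words are never emitted.  One-letter "Character-Number-Character"
    matches are suppressed when one of the two preceding tokens is a
    figure/table/chemical cue word.
    """
    mentions: list[Mention] = []
    for tok in doc.tokens:
        if not _token_is_variant(tok.surface):
            continue
        if _P_PROT1.match(tok.surface) and not (
            _P_PROT3.match(tok.surface)
            or tok.surface.startswith("p.")
        ):
            preceding = [
                doc.tokens[j].surface.lower()
                for j in range(max(0, tok.index - 2), tok.index)
            ]
            if any(p in _CUE_WORDS for p in preceding):
                continue
        key = normalize_variant(tok.surface)
        mentions.append(
            Mention(
                entity_class=EntityClass.VARIANT,
                surface=tok.surface,
                normalized_id=key.canonical,
                location=doc.locate(tok.char_start, tok.char_end),
                source=MentionSource.BUILTIN,
            )
        )
    return mentions


def dictionary_match(
    doc: Document,
    lexicon: dict[str, str],
    entity_class: EntityClass,
) -> list[Mention]:
    """Longest-match-first lexicon tagging over token sequences.

    Gene symbols of length <= 4 are matched case-sensitively (short symbols
    like "WAS" or "KIT" collide with common words); all other terms match
    case-insensitively.  Matches never overlap: at each position the longest
    matching term wins and the scan resumes after it.
    """
    if not lexicon:
        raise ValueError("lexicon is empty")

    # index lexicon terms by their token sequences
    from .corpus_io import _TOKEN_RE  # same tokenizer as documents

    term_index: dict[tuple[str, ...], tuple[str, str, bool]] = {}
    max_len = 1
    for term, ident in lexicon.items():
        toks = tuple(m.group(0) for m in _TOKEN_RE.finditer(term))
        if not toks:
            continue
        case_sensitive = entity_class is EntityClass.GENE and len(term) <= 4
        key = toks if case_sensitive else tuple(t.lower() for t in toks)
        term_index[key] = (term, ident, case_sensitive)
        max_len = max(max_len, len(toks))

    mentions: list[Mention] = []
    for par in doc.paragraphs:
        for sent in par.sentences:
            i = sent.token_start
            while i < sent.token_end:
                matched = None
                for length in range(min(max_len, sent.token_end - i), 0, -1):
                    window = doc.tokens[i : i + length]
                    exact = tuple(t.surface for t in window)
                    lowered = tuple(t.surface.lower() for t in window)
                    hit = None
                    if exact in term_index and term_index[exact][2]:
                        hit = term_index[exact]
                    elif lowered in term_index and not term_index[lowered][2]:
                        hit = term_index[lowered]
                    if hit is not None:
                        matched = (length, hit)
                        break
                if matched is None:
                    i += 1
                    continue
                length, (_, ident, _) = matched
                start = doc.tokens[i].char_start
                end = doc.tokens[i + length - 1].char_end
                mentions.append(
                    Mention(
                        entity_class=entity_class,
                        surface=doc.full_text[start:end],
                        normalized_id=ident,
                        location=doc.locate(start, end),
                        source=MentionSource.BUILTIN,
                    )
                )
                i += length
    return mentions
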