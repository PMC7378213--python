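"""Article parsing: segmented document model and standoff-annotation ingest.

Articles are represented as a :class:`Document` — an ordered hierarchy of
paragraphs, sentences and tokens, every one carrying 0-based half-open
character offsets into a single ``full_text`` string.  The offsets are the
backbone of everything downstream: proximity features between entity
mentions (same sentence / same paragraph / token distance) are computed from
them, so the invariant that every token's surface equals the ``full_text``
substring at its span is enforced at construction time.

Two input channels are supported:

* line-delimited JSON records (``doc_id``, ``title``, ``abstract``, ``body``)
  or plain-text files, parsed with the built-in segmenter;
* PubTator standoff annotation files, the tab-separated format emitted by
  tmVar / GNormPlus / DNorm-class entity recognizers, ingested as external
  mentions that take precedence over the built-in recognizers.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, TextIO

__all__ = [
    "Section",
    "EntityClass",
    "MentionSource",
    "Token",
    "Sentence",
    "Paragraph",
    "Location",
    "Mention",
    "Document",
    "SegmentationRules",
    "parse_document",
    "read_jsonl_corpus",
    "read_plain_text",
    "PubTatorIngest",
    "read_pubtator",
]


class Section(str, Enum):
    TITLE = "TITLE"
    ABSTRACT = "ABSTRACT"
    BODY = "BODY"


class EntityClass(str, Enum):
    VARIANT = "VARIANT"
    GENE = "GENE"
    DISEASE = "DISEASE"


class MentionSource(str, Enum):
    BUILTIN = "BUILTIN"
    EXTERNAL = "EXTERNAL"


# A token is a maximal run of alphanumerics possibly joined by internal
# punctuation.  Hyphens, slashes, dots, '>' etc. inside alphanumeric strings
# do NOT split, so variant surfaces like "c.123A>G", "p.Ala123Val" and
# "rs12345" survive as single tokens; a trailing sentence period does not
# attach because the final character must be alphanumeric or '>'.
_TOKEN_RE = re.compile(r"[A-Za-z0-9](?:[A-Za-z0-9._>\-/+*']*[A-Za-z0-9>])?")

# Sentence boundary: terminal punctuation, whitespace, then an uppercase
# letter, digit or opening quote/paren.  Boundaries after known
# abbreviations are suppressed.
_SENT_BOUNDARY_RE = re.compile(r"[.!?]+(?=\s+[\"(\[]?[A-Z0-9])")

_DEFAULT_ABBREVIATIONS = frozenset(
    {
        "fig", "figs", "al", "e.g", "i.e", "vs", "dr", "no", "ref", "refs",
        "approx", "ca", "cf", "resp", "st", "jr",
    }
)


@dataclass(frozen=True)
class Token:
    surface: str
    char_start: int
    char_end: int
    index: int  # document-global token index


@dataclass(frozen=True)
class Sentence:
    index: int  # within paragraph
    char_start: int
    char_end: int
    token_start: int  # document-global, half-open
    token_end: int


@dataclass(frozen=True)
class Paragraph:
    section: Section
    index: int  # document-global paragraph index
    char_start: int
    char_end: int
    sentences: tuple[Sentence, ...]


@dataclass(frozen=True)
class Location:
    """Where a mention sits: section, paragraph/sentence indices, spans."""

    section: Section
    paragraph_index: int
    sentence_index: int
    char_start: int
    char_end: int
    token_start: int
    token_end: int

    def __post_init__(self) -> None:
        if not self.char_start < self.char_end:
            raise ValueError("char_start must be < char_end")
        if not self.token_start < self.token_end:
            raise ValueError("token_start must be < token_end")


@dataclass(frozen=True)
class Mention:
    entity_class: EntityClass
    surface: str
    normalized_id: str
    location: Location
    source: MentionSource = MentionSource.BUILTIN


@dataclass(frozen=True)
class SegmentationRules:
    paragraph_delimiter: str = r"\n\s*\n"
    abbreviations: frozenset[str] = _DEFAULT_ABBREVIATIONS


@dataclass
class Document:
    """A segmented article.  Offsets index into :attr:`full_text`."""

    doc_id: str
    title: str
    abstract: str
    full_text: str
    paragraphs: tuple[Paragraph, ...]
    tokens: tuple[Token, ...]

    @property
    def body_paragraphs(self) -> tuple[Paragraph, ...]:
        return tuple(p for p in self.paragraphs if p.section is Section.BODY)

    def iter_sentences(self) -> Iterator[tuple[Paragraph, Sentence]]:
        for par in self.paragraphs:
            for sent in par.sentences:
                yield par, sent

    def tokens_in(self, section: Section | None = None) -> list[Token]:
        if section is None:
            return list(self.tokens)
        out: list[Token] = []
        for par in self.paragraphs:
            if par.section is section:
                for sent in par.sentences:
                    out.extend(self.tokens[sent.token_start : sent.token_end])
        return out

    def locate(self, char_start: int, char_end: int) -> Location:
        """Build a Location for an arbitrary character span.

        The span must overlap at least one token and fall inside a single
        sentence (entity mentions never cross sentence boundaries here).
        """
        if not 0 <= char_start < char_end <= len(self.full_text):
            raise ValueError(
                f"span [{char_start}, {char_end}) outside document {self.doc_id!r}"
            )
        for par in self.paragraphs:
            if not (par.char_start <= char_start and char_end <= par.char_end):
                continue
            for sent in par.sentences:
                if sent.char_start <= char_start and char_end <= sent.char_end:
                    covered = [
                        t.index
                        for t in self.tokens[sent.token_start : sent.token_end]
                        if t.char_start < char_end and char_start < t.char_end
                    ]
                    if not covered:
                        break
                    return Location(
                        section=par.section,
                        paragraph_index=par.index,
                        sentence_index=sent.index,
                        char_start=char_start,
                        char_end=char_end,
                        token_start=covered[0],
                        token_end=covered[-1] + 1,
                    )
        raise ValueError(
            f"span [{char_start}, {char_end}) does not align with a sentence "
            f"in document {self.doc_id!r}"
        )


def _split_sentences(text: str, offset: int, abbreviations: frozenset[str]) -> list[tuple[int, int]]:
    """Character spans (absolute, via ``offset``) of sentences in a block."""
    boundaries: list[int] = []
    for m in _SENT_BOUNDARY_RE.finditer(text):
        before = text[: m.start()]
        word = re.search(r"[\w.]+$", before)
        if word and word.group(0).rstrip(".").lower() in abbreviations:
            continue
        boundaries.append(m.end())
    spans: list[tuple[int, int]] = []
    start = 0
    for b in boundaries:
        spans.append((start, b))
        start = b
    spans.append((start, len(text)))
    out = []
    for s, e in spans:
        # trim surrounding whitespace so sentence spans are tight
        seg = text[s:e]
        lstrip = len(seg) - len(seg.lstrip())
        rstrip = len(seg) - len(seg.rstrip())
        if seg.strip():
            out.append((offset + s + lstrip, offset + e - rstrip))
    return out


def parse_document(
    raw: Mapping[str, str],
    rules: SegmentationRules | None = None,
) -> Document:
    """Parse a raw record into a segmented :class:`Document`.

    ``raw`` carries ``doc_id``, ``title``, ``abstract`` and ``body``; the
    body is split into paragraphs on blank lines, paragraphs into sentences
    on terminal punctuation, sentences into tokens.  Deterministic for a
    fixed input and rule set.
    """
    rules = rules or SegmentationRules()
    doc_id = str(raw.get("doc_id", "") or "").strip()
    if not doc_id:
        raise ValueError("document has empty doc_id")
    title = str(raw.get("title", "") or "")
    abstract = str(raw.get("abstract", "") or "")
    body = str(raw.get("body", "") or "")

    para_re = re.compile(rules.paragraph_delimiter)

    segments: list[tuple[Section, str]] = []
    if title.strip():
        segments.append((Section.TITLE, title.strip()))
    for block in para_re.split(abstract):
        if block.strip():
            segments.append((Section.ABSTRACT, block.strip()))
    for block in para_re.split(body):
        if block.strip():
            segments.append((Section.BODY, block.strip()))

    full_text = "\n\n".join(text for _, text in segments)

    paragraphs: list[Paragraph] = []
    tokens: list[Token] = []
    cursor = 0
    for p_idx, (section, text) in enumerate(segments):
        p_start = full_text.index(text, cursor)
        p_end = p_start + len(text)
        cursor = p_end
        sentences: list[Sentence] = []
        for s_idx, (s_start, s_end) in enumerate(
            _split_sentences(text, p_start, rules.abbreviations)
        ):
            tok_start = len(tokens)
            for m in _TOKEN_RE.finditer(full_text, s_start, s_end):
                tokens.append(
                    Token(
                        surface=m.group(0),
                        char_start=m.start(),
                        char_end=m.end(),
                        index=len(tokens),
                    )
                )
            sentences.append(
                Sentence(
                    index=s_idx,
                    char_start=s_start,
                    char_end=s_end,
                    token_start=tok_start,
                    token_end=len(tokens),
                )
            )
        paragraphs.append(
            Paragraph(
                section=section,
                index=p_idx,
                char_start=p_start,
                char_end=p_end,
                sentences=tuple(sentences),
            )
        )

    doc = Document(
        doc_id=doc_id,
        title=title,
        abstract=abstract,
        full_text=full_text,
        paragraphs=tuple(paragraphs),
        tokens=tuple(tokens),
    )
    for tok in doc.tokens:
        assert full_text[tok.char_start : tok.char_end] == tok.surface
    return doc


def read_jsonl_corpus(
    path: str | Path, rules: SegmentationRules | None = None
) -> list[Document]:
    """Read a line-delimited JSON corpus (one record per line)."""
    docs: list[Document] = []
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            try:
                record = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{ln}: undecodable record: {exc}") from exc
            docs.append(parse_document(record, rules))
    return docs


def read_plain_text(
    path: str | Path, rules: SegmentationRules | None = None
) -> Document:
    """Read a plain-text article: stem = doc_id, first line = title,
    second blank-line block = abstract, the rest = body."""
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
    except UnicodeDecodeError as exc:
        raise ValueError(f"undecodable text in document {path.stem!r}: {exc}") from exc
    blocks = re.split(r"\n\s*\n", text, maxsplit=2)
    title = blocks[0].strip() if blocks else ""
    abstract = blocks[1].strip() if len(blocks) > 1 else ""
    body = blocks[2] if len(blocks) > 2 else ""
    return parse_document(
        {"doc_id": path.stem, "title": title, "abstract": abstract, "body": body},
        rules,
    )


_PUBTATOR_TYPE_MAP = {
    "Mutation": EntityClass.VARIANT,
    "SNP": EntityClass.VARIANT,
    "DNAMutation": EntityClass.VARIANT,
    "ProteinMutation": EntityClass.VARIANT,
    "Gene": EntityClass.GENE,
    "Disease": EntityClass.DISEASE,
}


@dataclass
class PubTatorIngest:
    """Result of reading a PubTator annotation stream.

    ``mentions`` maps doc_id to the accepted external mentions;
    the counters record annotations dropped and why.
    """

    mentions: dict[str, list[Mention]] = field(default_factory=dict)
    documents: dict[str, Document] = field(default_factory=dict)
    n_rejected_offsets: int = 0
    n_malformed: int = 0
    n_unknown_type: int = 0
    warnings: list[str] = field(default_factory=list)


def read_pubtator(
    stream: TextIO | Iterable[str],
    documents: Mapping[str, Document] | None = None,
) -> PubTatorIngest:
    """Ingest PubTator-format standoff annotations as external mentions.

    The stream interleaves ``id|t|title`` / ``id|a|abstract`` text lines with
    tab-separated annotation lines ``id, start, end, surface, type, norm_id``.
    Offsets follow the PubTator convention of indexing ``title + " " +
    abstract``.  When ``documents`` is given, annotations are anchored into
    those parsed documents; otherwise documents are built from the stream's
    own title/abstract lines.  Annotations whose surface does not match the
    document text at the stated offsets are rejected and counted.
    """
    ingest = PubTatorIngest()
    titles: dict[str, str] = {}
    abstracts: dict[str, str] = {}
    annotations: list[tuple[str, int, int, str, str, str]] = []

    for line in stream:
        line = line.rstrip("\n")
        if not line.strip():
            continue
        m = re.match(r"^([^|\t]+)\|([ta])\|(.*)$", line)
        if m:
            doc_id, kind, text = m.groups()
            (titles if kind == "t" else abstracts)[doc_id] = text
            continue
        parts = line.split("\t")
        if len(parts) < 6:
            ingest.n_malformed += 1
            ingest.warnings.append(f"malformed annotation line skipped: {line!r}")
            continue
        doc_id, start_s, end_s, surface, ann_type = parts[0], parts[1], parts[2], parts[3], parts[4]
        norm_id = parts[5]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            ingest.n_malformed += 1
            ingest.warnings.append(f"non-integer offsets skipped: {line!r}")
            continue
        annotations.append((doc_id, start, end, surface, ann_type, norm_id))

    if documents is None:
        docs: dict[str, Document] = {}
        for doc_id in {a[0] for a in annotations} | set(titles) | set(abstracts):
            docs[doc_id] = parse_document(
                {
                    "doc_id": doc_id,
                    "title": titles.get(doc_id, ""),
                    "abstract": abstracts.get(doc_id, ""),
                    "body": "",
                }
            )
        documents = docs
    ingest.documents = dict(documents)

    for doc_id, start, end, surface, ann_type, norm_id in annotations:
        if ann_type not in _PUBTATOR_TYPE_MAP:
            ingest.n_unknown_type += 1
            ingest.warnings.append(f"{doc_id}: unknown annotation type {ann_type!r}")
            continue
        doc = documents.get(doc_id)
        if doc is None:
            ingest.n_rejected_offsets += 1
            ingest.warnings.append(f"{doc_id}: no document for annotation")
            continue
        # translate PubTator offsets (title + ' ' + abstract) into full_text
        # offsets (title + '\n\n' + abstract)
        title = doc.title.strip()
        shift = 1 if (title and start > len(title)) else 0
        fs, fe = start + shift, end + shift
        if not (
            0 <= fs < fe <= len(doc.full_text)
            and doc.full_text[fs:fe] == surface
        ):
            ingest.n_rejected_offsets += 1
            ingest.warnings.append(
                f"{doc_id}: annotation {surface!r} at [{start},{end}) does not "
                f"match document text"
            )
            continue
        try:
            loc = doc.locate(fs, fe)
        except ValueError:
            ingest.n_rejected_offsets += 1
            ingest.warnings.append(
                f"{doc_id}: annotation {surface!r} does not align with a sentence"
            )
            continue
        ingest.mentions.setdefault(doc_id, []).append(
            Mention(
                entity_class=_PUBTATOR_TYPE_MAP[ann_type],
                surface=surface,
                normalized_id=norm_id,
                location=loc,
                source=MentionSource.EXTERNAL,
            )
        )
    return ingest
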