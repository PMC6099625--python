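"""Reading and writing the PubTator annotation exchange format.

PubTator is the line-oriented format used by NCBI's literature annotation
services.  A document block looks like::

    <id>|t|<title>
    <id>|a|<abstract or full text>
    <id><TAB><start><TAB><end><TAB><mention><TAB><type>[<TAB><concept id>]
    ...

Blocks are separated by blank lines.  Annotation offsets are 0-based,
end-exclusive character offsets into the *composite text*: the title, one
space character, then the body (title alone when the body is empty).
Characters means decoded text characters, not bytes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Iterator, Sequence

from lxml import etree

logger = logging.getLogger(__name__)

_WS_RUN = re.compile(r"\s+")

__all__ = [
    "Document",
    "Annotation",
    "AnnotatedDocument",
    "PubTatorFormatError",
    "read_pubtator",
    "write_pubtator",
    "nxml_to_document",
    "merge_annotations",
]


class PubTatorFormatError(ValueError):
    """Malformed PubTator or NXML input.

    Carries the 1-based line number of the offending line when known.
    """

    def __init__(self, message: str, line_no: int | None = None):
        self.line_no = line_no
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)


def _clean_text(text: str) -> str:
    """Collapse whitespace runs (incl. newlines) to single spaces and strip."""
    return _WS_RUN.sub(" ", text).strip()


@dataclass(frozen=True)
class Document:
    """One article: identifier, title, and body (abstract or full text)."""

    doc_id: str
    title: str
    body: str = ""

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")
        if any(c in self.doc_id for c in "|\t\n"):
            raise ValueError(f"doc_id {self.doc_id!r} contains '|', tab or newline")
        for name in ("title", "body"):
            if "\n" in getattr(self, name):
                raise ValueError(f"{name} must not contain newlines")

    @property
    def composite_text(self) -> str:
        """Title + one space + body; title alone when the body is empty.

        This is the string annotation offsets index into, and whose length
        is the document's size in characters.
        """
        if not self.body:
            return self.title
        return f"{self.title} {self.body}"

    @property
    def size_chars(self) -> int:
        return len(self.composite_text)


@dataclass(frozen=True, order=True)
class Annotation:
    """One recognized entity mention with its character span."""

    doc_id: str
    start: int
    end: int
    mention: str
    entity_type: str
    concept_id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")
        if not self.entity_type:
            raise ValueError("entity_type must be non-empty")

    def validate_against(self, doc: Document) -> None:
        """Check that the span indexes the mention in doc's composite text."""
        if self.doc_id != doc.doc_id:
            raise ValueError(
                f"annotation doc_id {self.doc_id!r} != document {doc.doc_id!r}"
            )
        text = doc.composite_text
        if self.end > len(text):
            raise ValueError(
                f"span [{self.start}, {self.end}) exceeds text length {len(text)}"
            )
        found = text[self.start : self.end]
        if found != self.mention:
            raise ValueError(
                f"mention {self.mention!r} != text[{self.start}:{self.end}] = {found!r}"
            )


@dataclass(frozen=True)
class AnnotatedDocument:
    """A document together with its annotations, sorted by (start, end)."""

    document: Document
    annotations: tuple[Annotation, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        anns = tuple(sorted(self.annotations, key=lambda a: (a.start, a.end)))
        object.__setattr__(self, "annotations", anns)
        for a in anns:
            if a.doc_id != self.document.doc_id:
                raise ValueError(
                    f"annotation for {a.doc_id!r} attached to {self.document.doc_id!r}"
                )


def _iter_blocks(lines: Iterable[str]) -> Iterator[list[tuple[int, str]]]:
    """Group numbered lines into blank-line-separated blocks."""
    block: list[tuple[int, str]] = []
    for no, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if line.strip() == "":
            if block:
                yield block
                block = []
        else:
            block.append((no, line))
    if block:
        yield block


def _parse_block(block: list[tuple[int, str]]) -> AnnotatedDocument:
    no, first = block[0]
    m = re.match(r"^([^|\t]+)\|t\|(.*)$", first)
    if m is None:
        raise PubTatorFormatError(f"expected '<id>|t|<title>' line, got {first!r}", no)
    doc_id, title = m.group(1), m.group(2)

    body = ""
    rest = block[1:]
    if rest:
        m = re.match(r"^([^|\t]+)\|a\|(.*)$", rest[0][1])
        if m is not None:
            a_no = rest[0][0]
            if m.group(1) != doc_id:
                raise PubTatorFormatError(
                    f"abstract id {m.group(1)!r} != title id {doc_id!r}", a_no
                )
            body = m.group(2)
            rest = rest[1:]

    doc = Document(doc_id=doc_id, title=title, body=body)

    annotations = []
    for no, line in rest:
        fields = line.split("\t")
        if len(fields) not in (5, 6):
            raise PubTatorFormatError(
                f"annotation line has {len(fields)} tab-separated fields, expected 5 or 6",
                no,
            )
        ann_id, start_s, end_s, mention, etype = fields[:5]
        concept = fields[5] if len(fields) == 6 else ""
        if ann_id != doc_id:
            raise PubTatorFormatError(
                f"annotation doc_id {ann_id!r} != block id {doc_id!r}", no
            )
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise PubTatorFormatError(
                f"non-integer offsets {start_s!r}, {end_s!r}", no
            ) from None
        try:
            ann = Annotation(
                doc_id=ann_id,
                start=start,
                end=end,
                mention=mention,
                entity_type=etype,
                concept_id=concept,
            )
            ann.validate_against(doc)
        except ValueError as exc:
            raise PubTatorFormatError(str(exc), no) from None
        annotations.append(ann)

    return AnnotatedDocument(document=doc, annotations=tuple(annotations))


def read_pubtator(stream: IO[str] | str, strict: bool = True) -> list[AnnotatedDocument]:
    """Parse PubTator text into a list of annotated documents.

    Parameters
    ----------
    stream:
        An open text file or a string of PubTator content.
    strict:
        When True (default), any malformed block raises
        :class:`PubTatorFormatError`.  When False, offending blocks are
        skipped and logged, and the well-formed remainder is returned.
    """
    if isinstance(stream, str):
        lines: Iterable[str] = stream.splitlines()
    else:
        lines = stream
    out: list[AnnotatedDocument] = []
    for block in _iter_blocks(lines):
        try:
            out.append(_parse_block(block))
        except PubTatorFormatError as exc:
            if strict:
                raise
            logger.warning("skipping malformed PubTator block: %s", exc)
    return out


def write_pubtator(docs: Sequence[AnnotatedDocument], stream: IO[str]) -> None:
    """Write documents as PubTator blocks separated by blank lines.

    Annotation lines always carry 6 tab-separated fields (the concept id may
    be empty).  Every annotation is re-validated against its document's
    composite text before anything for that document is emitted.
    """
    for adoc in docs:
        doc = adoc.document
        for ann in adoc.annotations:
            ann.validate_against(doc)
        stream.write(f"{doc.doc_id}|t|{doc.title}\n")
        stream.write(f"{doc.doc_id}|a|{doc.body}\n")
        for ann in adoc.annotations:
            stream.write(
                f"{ann.doc_id}\t{ann.start}\t{ann.end}\t{ann.mention}"
                f"\t{ann.entity_type}\t{ann.concept_id}\n"
            )
        stream.write("\n")


_JATS_NS_STRIP = re.compile(r"\{[^}]*\}")


def _flatten(elem) -> str:
    """All text below an element, markup stripped, whitespace collapsed."""
    return _clean_text("".join(elem.itertext()))


def nxml_to_document(
    nxml: IO[bytes] | IO[str] | str | bytes,
    include_full_text: bool = False,
    fallback_id: str | None = None,
) -> Document:
    """Extract a PubTator-style document from a JATS/NXML article.

    The title is the flattened text of ``article-title``; the body is the
    flattened abstract, optionally followed by the body paragraphs joined
    with single spaces when ``include_full_text`` is set.  The id comes from
    the ``article-id`` element with ``pub-id-type="pmid"``, or from
    ``fallback_id``.
    """
    try:
        if isinstance(nxml, str):
            root = etree.fromstring(nxml.encode("utf-8"))
        elif isinstance(nxml, bytes):
            root = etree.fromstring(nxml)
        else:
            root = etree.parse(nxml).getroot()
    except etree.XMLSyntaxError as exc:
        name = getattr(nxml, "name", "<input>")
        raise PubTatorFormatError(f"unparseable NXML in {name}: {exc}") from exc

    def findall(path: str):
        # namespace-agnostic search: JATS articles appear both with and
        # without a default namespace in the wild
        return [
            e
            for e in root.iter()
            if _JATS_NS_STRIP.sub("", e.tag if isinstance(e.tag, str) else "") == path
        ]

    titles = findall("article-title")
    if not titles:
        raise PubTatorFormatError("NXML has no article-title element")
    title = _flatten(titles[0])

    doc_id = None
    for e in findall("article-id"):
        if e.get("pub-id-type") == "pmid" and e.text and e.text.strip():
            doc_id = e.text.strip()
            break
    if doc_id is None:
        if fallback_id is None:
            raise PubTatorFormatError("NXML has no pmid article-id and no fallback id")
        doc_id = fallback_id

    parts: list[str] = []
    abstracts = findall("abstract")
    if abstracts:
        parts.append(_flatten(abstracts[0]))
    if include_full_text:
        bodies = findall("body")
        if bodies:
            for p in bodies[0].iter():
                tag = _JATS_NS_STRIP.sub("", p.tag if isinstance(p.tag, str) else "")
                if tag == "p":
                    parts.append(_flatten(p))
    body = " ".join(s for s in parts if s)
    return Document(doc_id=doc_id, title=title, body=body)


def merge_annotations(
    doc: Document, per_plugin: Sequence[Sequence[Annotation]]
) -> AnnotatedDocument:
    """Union annotation lists from several plugins into one document block.

    Exact duplicates (same span, type and concept) collapse to one; output
    is sorted by (start, end, entity_type).  Overlapping spans of different
    types are all kept.
    """
    seen: dict[tuple, Annotation] = {}
    for plugin_anns in per_plugin:
        for ann in plugin_anns:
            ann.validate_against(doc)
            key = (ann.start, ann.end, ann.entity_type, ann.concept_id)
            seen.setdefault(key, ann)
    merged = sorted(seen.values(), key=lambda a: (a.start, a.end, a.entity_type))
    return AnnotatedDocument(document=doc, annotations=tuple(merged))
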