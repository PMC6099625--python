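"""Lightweight demonstration annotators.

These stand in for heavyweight NER tools (gene, mutation and disease
taggers) so the parallel pipeline can be exercised end to end.  They make no
claim to recognition accuracy: the pipeline treats annotators as black boxes
and only their cost and output plumbing matter here.

Word boundaries are transitions between alphanumeric and non-alphanumeric
characters — simpler than tokenization and sufficient for fixture text.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import IO, Iterable, Mapping

from .pubtator import Annotation, Document

__all__ = [
    "Lexicon",
    "load_lexicon",
    "bundled_lexicon",
    "regex_mutation_tagger",
    "lexicon_tagger",
    "MutationTagger",
    "LexiconTagger",
]


@dataclass(frozen=True)
class Lexicon:
    """Case-folded surface forms mapped to concept ids, for one entity type."""

    entries: Mapping[str, str]
    entity_type: str

    def __post_init__(self) -> None:
        for form in self.entries:
            if not form or form != form.strip():
                raise ValueError(f"bad lexicon surface form {form!r}")
        if not self.entity_type:
            raise ValueError("entity_type must be non-empty")


def load_lexicon(stream: IO[str] | Iterable[str], entity_type: str) -> Lexicon:
    """Read a two-column (surface form, concept id) tab-separated lexicon.

    Lines starting with '#' and blank lines are ignored; surface forms are
    case-folded on load.
    """
    entries: dict[str, str] = {}
    for line in stream:
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"expected 2 tab-separated columns, got {line!r}")
        form, concept = parts[0].strip().casefold(), parts[1].strip()
        entries[form] = concept
    return Lexicon(entries=entries, entity_type=entity_type)


def bundled_lexicon(name: str) -> Lexicon:
    """Load a fixture lexicon shipped with the package ('genes' or 'diseases')."""
    types = {"genes": "Gene", "diseases": "Disease"}
    if name not in types:
        raise ValueError(f"no bundled lexicon {name!r}; choose from {sorted(types)}")
    text = resources.files("textmill.data").joinpath(f"{name}.tsv").read_text("utf-8")
    return load_lexicon(text.splitlines(), entity_type=types[name])


def _is_word_char(c: str) -> bool:
    return c.isalnum()


def _at_word_boundary(text: str, start: int, end: int) -> bool:
    before_ok = start == 0 or not (
        _is_word_char(text[start - 1]) and _is_word_char(text[start])
    )
    after_ok = end == len(text) or not (
        _is_word_char(text[end - 1]) and _is_word_char(text[end])
    )
    return before_ok and after_ok


# protein substitution (V600E) and HGVS-like coding change (c.123A>G)
_SUBSTITUTION = re.compile(r"[A-Z][0-9]{1,5}[A-Z]")
_HGVS_CODING = re.compile(r"c\.[0-9]+[ACGT]>[ACGT]")


def regex_mutation_tagger(doc: Document) -> list[Annotation]:
    """Tag protein-substitution and HGVS-style mutation mentions.

    Candidate matches are filtered to word boundaries; overlaps resolve
    longest-first, then left-first.
    """
    text = doc.composite_text
    candidates: list[tuple[int, int]] = []
    for pattern in (_HGVS_CODING, _SUBSTITUTION):
        for m in pattern.finditer(text):
            if _at_word_boundary(text, m.start(), m.end()):
                candidates.append((m.start(), m.end()))
    candidates.sort(key=lambda se: (-(se[1] - se[0]), se[0]))
    taken: list[tuple[int, int]] = []
    chosen = []
    for start, end in candidates:
        if any(start < e and s < end for s, e in taken):
            continue
        taken.append((start, end))
        chosen.append(
            Annotation(
                doc_id=doc.doc_id,
                start=start,
                end=end,
                mention=text[start:end],
                entity_type="Mutation",
            )
        )
    chosen.sort(key=lambda a: (a.start, a.end))
    return chosen


def lexicon_tagger(doc: Document, lexicon: Lexicon) -> list[Annotation]:
    """Case-insensitive, longest-match-wins dictionary scan at word boundaries.

    Output annotations never overlap; each carries the lexicon's entity type
    and the matched entry's concept id.
    """
    if not lexicon.entries:
        raise ValueError("lexicon is empty")
    text = doc.composite_text
    folded = text.casefold()
    forms = sorted(lexicon.entries, key=len, reverse=True)
    out: list[Annotation] = []
    i = 0
    while i < len(folded):
        if not _is_word_char(folded[i]) or (
            i > 0 and _is_word_char(folded[i - 1])
        ):
            i += 1
            continue
        hit = None
        for form in forms:  # longest first
            end = i + len(form)
            if folded.startswith(form, i) and _at_word_boundary(text, i, end):
                hit = (end, form)
                break
        if hit is None:
            i += 1
            continue
        end, form = hit
        out.append(
            Annotation(
                doc_id=doc.doc_id,
                start=i,
                end=end,
                mention=text[i:end],
                entity_type=lexicon.entity_type,
                concept_id=lexicon.entries[form],
            )
        )
        i = end
    return out


class MutationTagger:
    """Plugin wrapper around :func:`regex_mutation_tagger`."""

    def init(self) -> None:  # nothing to load; regexes are module-level
        pass

    def annotate(self, doc: Document) -> list[Annotation]:
        return regex_mutation_tagger(doc)


class LexiconTagger:
    """Plugin wrapper around :func:`lexicon_tagger` with lazy dictionary load.

    The dictionary is loaded in :meth:`init`, once per worker, mimicking NER
    tools whose startup cost is dominated by loading large lexica.
    """

    def __init__(self, lexicon_name: str):
        self.lexicon_name = lexicon_name
        self._lexicon: Lexicon | None = None

    def init(self) -> None:
        self._lexicon = bundled_lexicon(self.lexicon_name)

    def annotate(self, doc: Document) -> list[Annotation]:
        if self._lexicon is None:
            raise RuntimeError("init() must run before annotate()")
        return lexicon_tagger(doc, self._lexicon)
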