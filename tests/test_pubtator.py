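"""PubTator parsing, writing, NXML extraction, and annotation merging."""

import io

import pytest
from hypothesis import given, settings, strategies as st

from textmill.pubtator import (
    AnnotatedDocument,
    Annotation,
    Document,
    PubTatorFormatError,
    merge_annotations,
    nxml_to_document,
    read_pubtator,
    write_pubtator,
)


class TestRead:
    def test_single_block_with_annotation(self):
        text = (
            "26094|t|BRAF V600E in melanoma.\n"
            "26094|a|We report the V600E mutation.\n"
            "26094\t5\t10\tV600E\tMutation\n"
        )
        (adoc,) = read_pubtator(text)
        assert adoc.document.doc_id == "26094"
        assert adoc.document.title == "BRAF V600E in melanoma."
        assert adoc.document.body == "We report the V600E mutation."
        (ann,) = adoc.annotations
        assert (ann.start, ann.end, ann.mention) == (5, 10, "V600E")

    def test_offsets_span_title_separator_body(self):
        # composite offset 38 = title length 23 + 1 separator + 14 into body
        text = (
            "26094|t|BRAF V600E in melanoma.\n"
            "26094|a|We report the V600E mutation.\n"
            "26094\t38\t43\tV600E\tMutation\n"
        )
        (adoc,) = read_pubtator(text)
        composite = adoc.document.composite_text
        assert composite.index("V600E", 11) == 38
        assert composite[38:43] == "V600E"

    def test_empty_stream(self):
        assert read_pubtator("") == []
        assert read_pubtator("\n\n\n") == []

    def test_multiple_blocks_order_preserved(self, sample_pubtator_text):
        docs = read_pubtator(sample_pubtator_text)
        assert [d.document.doc_id for d in docs] == ["26094", "31415", "27182"]
        assert docs[2].document.body == ""  # no abstract line

    def test_six_field_annotation_carries_concept(self):
        text = "1|t|BRAF V600E here.\n1|a|x\n1\t5\t10\tV600E\tMutation\tp.V600E\n"
        (adoc,) = read_pubtator(text)
        assert adoc.annotations[0].concept_id == "p.V600E"

    @pytest.mark.parametrize(
        "bad, match",
        [
            ("26094|x|oops\n", "t"),  # no |t| line
            ("1|t|ab c\n1\t0\tZZ\tab\tGene\n", "non-integer"),
            ("1|t|ab c\n1\t0\t2\txx\tGene\n", "mention"),
            ("1|t|ab c\n2\t0\t2\tab\tGene\n", "doc_id"),
            ("1|t|ab c\n1\t0\t2\tab\n", "fields"),
        ],
    )
    def test_malformed_input_strict_raises_with_line_number(self, bad, match):
        with pytest.raises(PubTatorFormatError, match="line"):
            read_pubtator(bad)
        with pytest.raises(PubTatorFormatError, match=match):
            read_pubtator(bad)

    def test_lenient_mode_skips_bad_blocks(self, sample_pubtator_text):
        text = "bad|x|nope\n\n" + sample_pubtator_text
        docs = read_pubtator(text, strict=False)
        assert [d.document.doc_id for d in docs] == ["26094", "31415", "27182"]


class TestWrite:
    def test_no_annotations_two_lines_plus_blank(self):
        doc = AnnotatedDocument(document=Document("9", "T", "A"))
        buf = io.StringIO()
        write_pubtator([doc], buf)
        assert buf.getvalue() == "9|t|T\n9|a|A\n\n"

    def test_annotation_lines_have_six_fields(self):
        doc = Document("1", "BRAF V600E here.", "x")
        ann = Annotation("1", 5, 10, "V600E", "Mutation", "p.V600E")
        buf = io.StringIO()
        write_pubtator([AnnotatedDocument(doc, (ann,))], buf)
        ann_line = buf.getvalue().splitlines()[2]
        assert len(ann_line.split("\t")) == 6

    def test_invalid_offset_aborts_before_writing(self):
        doc = Document("1", "short", "")
        bad = Annotation("1", 0, 99, "nope", "Gene")
        adoc = AnnotatedDocument(doc)
        object.__setattr__(adoc, "annotations", (bad,))
        buf = io.StringIO()
        with pytest.raises(ValueError, match="exceeds"):
            write_pubtator([adoc], buf)
        assert buf.getvalue() == ""

    def test_three_document_round_trip(self, sample_pubtator_text):
        docs = read_pubtator(sample_pubtator_text)
        buf = io.StringIO()
        write_pubtator(docs, buf)
        assert read_pubtator(buf.getvalue()) == docs


# --- property: read∘write is the identity --------------------------------

_text_alpha = st.text(
    alphabet=st.characters(
        codec="utf-8", exclude_characters="\n\t\r", categories=("L", "N", "P", "Zs")
    ),
    max_size=60,
)
_id_alpha = st.text(
    alphabet=st.characters(min_codepoint=48, max_codepoint=122, categories=("L", "N")),
    min_size=1,
    max_size=8,
)


@st.composite
def annotated_documents(draw):
    doc = Document(
        doc_id=draw(_id_alpha),
        title=draw(_text_alpha),
        body=draw(_text_alpha),
    )
    text = doc.composite_text
    anns = []
    if len(text) >= 1:
        for _ in range(draw(st.integers(0, 4))):
            start = draw(st.integers(0, len(text) - 1))
            end = draw(st.integers(start + 1, len(text)))
            mention = text[start:end]
            if "\t" in mention:
                continue
            anns.append(
                Annotation(
                    doc_id=doc.doc_id,
                    start=start,
                    end=end,
                    mention=mention,
                    entity_type=draw(st.sampled_from(["Gene", "Disease", "Mutation"])),
                    concept_id=draw(st.sampled_from(["", "673", "D008545"])),
                )
            )
    return AnnotatedDocument(document=doc, annotations=tuple(anns))


@settings(max_examples=200, derandomize=True)
@given(st.lists(annotated_documents(), max_size=5))
def test_round_trip_identity(docs):
    """read(write(x)) == x for arbitrary valid annotated documents."""
    # corpus-level invariant: unique ids keep blocks distinguishable
    buf = io.StringIO()
    write_pubtator(docs, buf)
    back = read_pubtator(buf.getvalue())
    assert back == list(docs)


@settings(max_examples=100, derandomize=True)
@given(annotated_documents())
def test_offset_soundness_after_read(adoc):
    """Every parsed annotation's mention equals the substring it indexes."""
    buf = io.StringIO()
    write_pubtator([adoc], buf)
    (back,) = read_pubtator(buf.getvalue())
    text = back.document.composite_text
    for ann in back.annotations:
        assert text[ann.start : ann.end] == ann.mention


# --- NXML extraction -------------------------------------------------------

MINIMAL_NXML = """<?xml version="1.0"?>
<article>
  <front><article-meta>
    <article-id pub-id-type="pmid">777</article-id>
    <title-group><article-title>T</article-title></title-group>
    <abstract><p>A</p></abstract>
  </article-meta></front>
</article>
"""

MARKUP_NXML = """<article>
  <front><article-meta>
    <article-id pub-id-type="pmid">778</article-id>
    <title-group><article-title>The <italic>BRAF</italic>
      gene</article-title></title-group>
    <abstract><p>Mutations   in <bold>melanoma</bold>.</p></abstract>
  </article-meta></front>
  <body><sec><p>First para.</p><p>Second  para.</p></sec></body>
</article>
"""


class TestNxml:
    def test_minimal(self):
        doc = nxml_to_document(MINIMAL_NXML)
        assert doc == Document("777", "T", "A")

    def test_inline_markup_stripped_whitespace_collapsed(self):
        doc = nxml_to_document(MARKUP_NXML)
        assert doc.title == "The BRAF gene"
        assert doc.body == "Mutations in melanoma."
        for banned in "<>\t\n":
            assert banned not in doc.title + doc.body

    def test_full_text_appends_body_paragraphs(self):
        doc = nxml_to_document(MARKUP_NXML, include_full_text=True)
        assert doc.body == "Mutations in melanoma. First para. Second para."

    def test_missing_title_errors(self):
        with pytest.raises(PubTatorFormatError, match="article-title"):
            nxml_to_document("<article><front/></article>")

    def test_missing_pmid_uses_fallback_else_errors(self):
        xml = "<article><article-title>T</article-title></article>"
        assert nxml_to_document(xml, fallback_id="f1").doc_id == "f1"
        with pytest.raises(PubTatorFormatError, match="pmid"):
            nxml_to_document(xml)

    def test_unparseable_xml_errors(self):
        with pytest.raises(PubTatorFormatError, match="unparseable"):
            nxml_to_document("<article><unclosed>")


# --- merging ----------------------------------------------------------------

class TestMerge:
    DOC = Document("1", "BRAF V600E in melanoma.", "We report the V600E mutation.")

    def a(self, start, end, etype, concept=""):
        text = self.DOC.composite_text
        return Annotation("1", start, end, text[start:end], etype, concept)

    def test_disjoint_union_sorted(self):
        g = [self.a(0, 4, "Gene", "673")]
        m = [self.a(5, 10, "Mutation"), self.a(38, 43, "Mutation")]
        merged = merge_annotations(self.DOC, [m, g])
        assert [x.start for x in merged.annotations] == [0, 5, 38]

    def test_exact_duplicates_collapse(self):
        ann = self.a(5, 10, "Mutation")
        merged = merge_annotations(self.DOC, [[ann], [ann]])
        assert len(merged.annotations) == 1

    def test_overlapping_different_types_both_kept(self):
        pair = [self.a(5, 10, "Mutation"), self.a(5, 10, "Variant")]
        merged = merge_annotations(self.DOC, [pair[:1], pair[1:]])
        expected = {(a.start, a.end, a.entity_type, a.concept_id) for a in pair}
        got = {(a.start, a.end, a.entity_type, a.concept_id) for a in merged.annotations}
        assert got == expected

    def test_cross_document_annotation_rejected(self):
        alien = Annotation("2", 0, 4, "BRAF", "Gene")
        with pytest.raises(ValueError, match="doc_id"):
            merge_annotations(self.DOC, [[alien]])
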