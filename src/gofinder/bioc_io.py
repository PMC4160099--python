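"""BioC XML reading/writing and passage scoping primitives.

BioC organizes a collection into documents, passages and sentences, with
key-value "infon" metadata at each level.  Here the passage infon ``type``
carries the corpus section label (``front`` is the article title,
``abstract`` the abstract, ``title_2`` a subsection heading, ``paragraph``
body text, plus figure/table caption types).  Character offsets follow the
BioC convention: passage offsets are document-level and 0-based; sentence
offsets are stored passage-relative in memory and converted back to
document-level on write.

Gene lists may arrive as a document-level infon ``relevant-genes``
(comma-separated) or as a sidecar TSV of (doc_id, gene_symbol); the
sidecar wins on conflict.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, IO, Iterable, List, Optional, Sequence, Tuple, Union

from lxml import etree

logger = logging.getLogger(__name__)

__all__ = [
    "KNOWN_PASSAGE_TYPES",
    "Sentence",
    "Passage",
    "Document",
    "BiocParseError",
    "read_bioc",
    "write_bioc",
    "abstract_text",
    "first_sentence",
    "write_predictions",
    "read_predictions",
    "read_gene_sidecar",
    "apply_gene_sidecar",
]

KNOWN_PASSAGE_TYPES = frozenset({
    "front", "abstract", "title_1", "title_2", "title_3", "title_4",
    "paragraph", "fig_title_caption", "fig_caption", "table_title_caption",
    "other",
})

# "title2" and friends appear in the wild; canonicalize to underscore form.
_TYPE_ALIASES = {f"title{i}": f"title_{i}" for i in range(1, 5)}


class BiocParseError(ValueError):
    """Malformed BioC XML, reported with document context where known."""


@dataclass(frozen=True)
class Sentence:
    text: str
    offset: int = 0  # passage-relative, 0-based
    index_in_passage: int = 0


@dataclass
class Passage:
    passage_type: str
    sentences: List[Sentence]
    offset: int = 0  # document-level, 0-based


@dataclass
class Document:
    doc_id: str
    passages: List[Passage]
    genes: List[str] = field(default_factory=list)


def canonical_passage_type(raw: Optional[str]) -> str:
    if raw is None:
        return "other"
    t = _TYPE_ALIASES.get(raw.strip(), raw.strip())
    if t not in KNOWN_PASSAGE_TYPES:
        logger.warning("unknown passage type %r mapped to 'other'", raw)
        return "other"
    return t


_SENT_SPLIT = re.compile(r"(?<=[.?!])\s+(?=[A-Z])")


def _fallback_sentences(text: str) -> List[Sentence]:
    pieces = [p for p in _SENT_SPLIT.split(text) if p.strip()]
    out: List[Sentence] = []
    cursor = 0
    for i, piece in enumerate(pieces):
        start = text.index(piece, cursor)
        out.append(Sentence(text=piece, offset=start, index_in_passage=i))
        cursor = start + len(piece)
    return out


def _infons(elem) -> Dict[str, str]:
    return {i.get("key"): (i.text or "") for i in elem.findall("infon")}


def read_bioc(stream: Union[str, bytes, IO]) -> List[Document]:
    """Parse a BioC XML collection into :class:`Document` objects.

    Passages lacking ``<sentence>`` elements get their ``<text>`` split by
    a period/question/exclamation + capital-letter heuristic, with a
    warning.  A missing ``type`` infon maps the passage to ``other``.
    """
    try:
        if isinstance(stream, (str, bytes)):
            root = etree.fromstring(
                stream.encode("utf-8") if isinstance(stream, str) else stream)
        else:
            root = etree.parse(stream).getroot()
    except etree.XMLSyntaxError as exc:
        raise BiocParseError(f"malformed BioC XML: {exc}") from exc

    documents: List[Document] = []
    for doc_elem in root.findall("document"):
        doc_id = (doc_elem.findtext("id") or "").strip()
        try:
            passages = [_read_passage(p, doc_id) for p in doc_elem.findall("passage")]
        except BiocParseError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise BiocParseError(f"document {doc_id!r}: {exc}") from exc
        genes_infon = _infons(doc_elem).get("relevant-genes", "")
        genes = [g.strip() for g in genes_infon.split(",") if g.strip()]
        documents.append(Document(doc_id=doc_id, passages=passages, genes=genes))
    return documents


def _read_passage(p_elem, doc_id: str) -> Passage:
    infons = _infons(p_elem)
    ptype = canonical_passage_type(infons.get("type"))
    offset = int(p_elem.findtext("offset") or 0)
    sentences: List[Sentence] = []
    sent_elems = p_elem.findall("sentence")
    if sent_elems:
        for i, s_elem in enumerate(sent_elems):
            text = s_elem.findtext("text") or ""
            if not text:
                continue
            s_offset = int(s_elem.findtext("offset") or offset)
            sentences.append(Sentence(
                text=text, offset=max(0, s_offset - offset), index_in_passage=i))
    else:
        text = p_elem.findtext("text") or ""
        if text:
            logger.warning(
                "document %s: passage at offset %d has no sentences; "
                "falling back to heuristic splitting", doc_id, offset)
            sentences = _fallback_sentences(text)
    return Passage(passage_type=ptype, sentences=sentences, offset=offset)


def write_bioc(documents: Sequence[Document], stream: IO[bytes]) -> None:
    """Serialize documents back to BioC XML (inverse of :func:`read_bioc`)."""
    root = etree.Element("collection")
    etree.SubElement(root, "source").text = "gofinder"
    for doc in documents:
        doc_elem = etree.SubElement(root, "document")
        etree.SubElement(doc_elem, "id").text = doc.doc_id
        if doc.genes:
            infon = etree.SubElement(doc_elem, "infon", key="relevant-genes")
            infon.text = ",".join(doc.genes)
        for passage in doc.passages:
            p_elem = etree.SubElement(doc_elem, "passage")
            t_infon = etree.SubElement(p_elem, "infon", key="type")
            t_infon.text = passage.passage_type
            etree.SubElement(p_elem, "offset").text = str(passage.offset)
            for sent in passage.sentences:
                s_elem = etree.SubElement(p_elem, "sentence")
                etree.SubElement(s_elem, "offset").text = str(
                    passage.offset + sent.offset)
                etree.SubElement(s_elem, "text").text = sent.text
    stream.write(etree.tostring(root, xml_declaration=True,
                                encoding="UTF-8", pretty_print=True))


def abstract_text(document: Document) -> str:
    """Space-joined text of all ``abstract`` passages, in document order.

    Falls back to the ``front`` passage (with a warning) when the document
    has no abstract, so the document-level candidate set D can still be
    computed; empty string if neither exists.
    """
    parts = [s.text for p in document.passages if p.passage_type == "abstract"
             for s in p.sentences]
    if parts:
        return " ".join(parts)
    front = [s.text for p in document.passages if p.passage_type == "front"
             for s in p.sentences]
    if front:
        logger.warning("document %s: no abstract passage; using front text",
                       document.doc_id)
        return " ".join(front)
    return ""


def first_sentence(passage: Passage) -> Sentence:
    if not passage.sentences:
        raise ValueError("passage has no sentences")
    return passage.sentences[0]


# ---------------------------------------------------------------------------
# Prediction output: one BioC annotation per (gene, sentence, GO id) triple.
# Schema (versioned here, used by read_predictions): annotation infons
# gene, go-id, score (6 decimals), passage-index, sentence-index; the
# annotation location carries the document-level evidence-sentence offset.
# ---------------------------------------------------------------------------

PREDICTION_SCHEMA_VERSION = "1"


def write_predictions(predictions: Sequence, stream: IO[bytes]) -> None:
    """Write predictions as a BioC collection, grouped by document."""
    root = etree.Element("collection")
    etree.SubElement(root, "source").text = "gofinder-predictions"
    version = etree.SubElement(root, "infon", key="prediction-schema-version")
    version.text = PREDICTION_SCHEMA_VERSION
    by_doc: Dict[str, list] = {}
    for pred in predictions:
        by_doc.setdefault(pred.doc_id, []).append(pred)
    for doc_id in sorted(by_doc):
        doc_elem = etree.SubElement(root, "document")
        etree.SubElement(doc_elem, "id").text = doc_id
        p_elem = etree.SubElement(doc_elem, "passage")
        etree.SubElement(p_elem, "infon", key="type").text = "other"
        etree.SubElement(p_elem, "offset").text = "0"
        for i, pred in enumerate(by_doc[doc_id]):
            a_elem = etree.SubElement(p_elem, "annotation", id=f"A{i}")
            for key, value in (
                ("gene", pred.gene),
                ("go-id", pred.go_id),
                ("score", f"{pred.score:.6f}"),
                ("passage-index", str(pred.sentence_ref[0])),
                ("sentence-index", str(pred.sentence_ref[1])),
            ):
                etree.SubElement(a_elem, "infon", key=key).text = value
            etree.SubElement(a_elem, "location",
                             offset=str(pred.sentence_offset), length="0")
    stream.write(etree.tostring(root, xml_declaration=True,
                                encoding="UTF-8", pretty_print=True))


def read_predictions(stream: Union[str, bytes, IO]) -> List:
    """Inverse of :func:`write_predictions`."""
    from .go_finder import Prediction  # deferred: go_finder imports this module

    try:
        if isinstance(stream, (str, bytes)):
            root = etree.fromstring(
                stream.encode("utf-8") if isinstance(stream, str) else stream)
        else:
            root = etree.parse(stream).getroot()
    except etree.XMLSyntaxError as exc:
        raise BiocParseError(f"malformed prediction XML: {exc}") from exc
    out: List = []
    for doc_elem in root.findall("document"):
        doc_id = (doc_elem.findtext("id") or "").strip()
        for a_elem in doc_elem.iter("annotation"):
            infons = _infons(a_elem)
            location = a_elem.find("location")
            out.append(Prediction(
                doc_id=doc_id,
                gene=infons["gene"],
                sentence_ref=(int(infons["passage-index"]),
                              int(infons["sentence-index"])),
                go_id=infons["go-id"],
                score=float(infons["score"]),
                sentence_offset=int(location.get("offset", "0"))
                if location is not None else 0,
            ))
    return out


def read_gene_sidecar(stream: Union[str, IO[str]]) -> Dict[str, List[str]]:
    """Read a TSV of (doc_id, gene_symbol) into doc_id -> symbols."""
    text = stream if isinstance(stream, str) else stream.read()
    mapping: Dict[str, List[str]] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"gene sidecar line {lineno}: expected 2 columns")
        doc_id, symbol = fields[0].strip(), fields[1].strip()
        if symbol and symbol not in mapping.setdefault(doc_id, []):
            mapping[doc_id].append(symbol)
    return mapping


def apply_gene_sidecar(documents: Iterable[Document],
                       sidecar: Dict[str, List[str]]) -> None:
    """Attach sidecar gene lists; the sidecar wins over document infons."""
    for doc in documents:
        if doc.doc_id in sidecar:
            doc.genes = list(sidecar[doc.doc_id])
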