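"""Per-(gene, sentence) GO term prediction by candidate-set intersection.

For a sentence known to mention a gene, two candidate sets are formed in
the semantic space:

* ``G`` — the top *m* concepts most similar to the sentence, and
* ``D`` — the top *n* concepts most similar to the whole abstract of the
  article (computed once per document and cached).

The predicted set for the (gene, sentence) pair is ``G ∩ D`` (empty when
the sentence does not mention the gene), and the single emitted annotation
is the member of that intersection most similar to the sentence.  The
intersection trades recall for precision: a concept must be locally
similar to the sentence *and* globally plausible for the article.

Searching is scoped by passage type.  The FAT sections — **F**ront (the
article title), **A**bstract and **T**itle_2 (subsection headings) — are
the densest in gene-function statements and get their own (m_fat, n_fat)
parameter pair; paragraph text contributes only selected sentences (by
default the first of each paragraph) under a separate
(m_paragraph, n_paragraph) pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

from .bioc_io import Document, Passage, Sentence, abstract_text, first_sentence
from .gene_matcher import GeneQuery, has_gene
from .semantic_space import SemanticSpace, cosine, embed_text, top_similar_go

logger = logging.getLogger(__name__)

__all__ = [
    "FinderParams",
    "Scope",
    "ScopedSentence",
    "Prediction",
    "SCOPE_MODES",
    "select_scope",
    "candidate_sets",
    "intersect_candidates",
    "gene_go",
    "final_annotation",
    "annotate_document",
    "annotate_corpus",
    "document_level_predictions",
]

FAT_PASSAGE_TYPES = frozenset({"front", "abstract", "title_2"})

#: Scope modes mirroring the evaluated configurations: which passage
#: sentences are searched besides the always-included FAT sections.
SCOPE_MODES = (
    "fat",             # FAT sections only
    "first+fat",       # + first sentence of each paragraph (default)
    "last+fat",        # + last sentence of each paragraph
    "first_last+fat",  # + first and last sentences
    "all+fat",         # + every paragraph sentence
    "paragraph",       # paragraph sentences only, no FAT
    "all_sections",    # every sentence of every passage
)


@dataclass(frozen=True)
class FinderParams:
    """The four tuning parameters: top-m per sentence, top-n per abstract,
    one (m, n) pair for FAT sections and one for paragraph sentences."""

    m_fat: int = 9
    n_fat: int = 75
    m_paragraph: int = 2
    n_paragraph: int = 15

    def __post_init__(self) -> None:
        for name in ("m_fat", "n_fat", "m_paragraph", "n_paragraph"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


class Scope(str, Enum):
    FAT = "FAT"
    PARAGRAPH_FIRST = "PARAGRAPH_FIRST"


@dataclass(frozen=True)
class ScopedSentence:
    sentence: Sentence
    scope: Scope
    passage_type: str
    passage_index: int
    passage_offset: int = 0


@dataclass(frozen=True)
class Prediction:
    doc_id: str
    gene: str
    sentence_ref: Tuple[int, int]  # (passage index, sentence index)
    go_id: str
    score: float
    sentence_offset: int = 0  # document-level offset of the evidence sentence


def _paragraph_pick(passage: Passage, mode: str) -> List[Sentence]:
    if not passage.sentences:
        return []
    if mode in ("all+fat", "all_sections"):
        return list(passage.sentences)
    if mode == "last+fat":
        return [passage.sentences[-1]]
    if mode == "first_last+fat":
        picked = [first_sentence(passage)]
        if len(passage.sentences) > 1:
            picked.append(passage.sentences[-1])
        return picked
    # "first+fat" and "paragraph" take the first sentence
    return [first_sentence(passage)]


def select_scope(document: Document, mode: str = "first+fat") -> List[ScopedSentence]:
    """Sentences to search under *mode*, tagged FAT or paragraph scope."""
    if mode not in SCOPE_MODES:
        raise ValueError(f"unknown scope mode {mode!r}; one of {SCOPE_MODES}")
    scoped: List[ScopedSentence] = []
    for p_index, passage in enumerate(document.passages):
        is_fat = passage.passage_type in FAT_PASSAGE_TYPES
        if is_fat:
            if mode == "paragraph":
                continue
            for sent in passage.sentences:
                scoped.append(ScopedSentence(
                    sentence=sent, scope=Scope.FAT,
                    passage_type=passage.passage_type,
                    passage_index=p_index, passage_offset=passage.offset))
        elif passage.passage_type == "paragraph":
            if mode == "fat":
                continue
            for sent in _paragraph_pick(passage, mode):
                scoped.append(ScopedSentence(
                    sentence=sent, scope=Scope.PARAGRAPH_FIRST,
                    passage_type=passage.passage_type,
                    passage_index=p_index, passage_offset=passage.offset))
        elif mode == "all_sections":
            for sent in passage.sentences:
                scoped.append(ScopedSentence(
                    sentence=sent, scope=Scope.PARAGRAPH_FIRST,
                    passage_type=passage.passage_type,
                    passage_index=p_index, passage_offset=passage.offset))
    return scoped


def _params_for(scoped: ScopedSentence, params: FinderParams) -> Tuple[int, int]:
    if scoped.scope is Scope.FAT:
        return params.m_fat, params.n_fat
    return params.m_paragraph, params.n_paragraph


def candidate_sets(
    space: SemanticSpace,
    scoped: ScopedSentence,
    abstract: str,
    params: FinderParams,
    d_cache: Optional[Dict[int, FrozenSet[str]]] = None,
) -> Tuple[FrozenSet[str], FrozenSet[str]]:
    """(G, D): top-m concepts for the sentence, top-n for the abstract.

    *d_cache* (keyed by n) memoizes D within a document, since D depends
    only on the abstract and n.
    """
    m, n = _params_for(scoped, params)
    g_set = frozenset(acc for acc, _ in top_similar_go(space, scoped.sentence.text, m))
    d_set = None if d_cache is None else d_cache.get(n)
    if d_set is None:
        d_set = frozenset(acc for acc, _ in top_similar_go(space, abstract, n))
        if d_cache is not None:
            d_cache[n] = d_set
    return g_set, d_set


def intersect_candidates(
    g_set: Iterable[str], d_set: Iterable[str], gene_present: bool
) -> FrozenSet[str]:
    """GeneGO as a pure set operation: G ∩ D when the gene is mentioned,
    otherwise the empty set."""
    if not gene_present:
        return frozenset()
    return frozenset(g_set) & frozenset(d_set)


def gene_go(
    space: SemanticSpace,
    gene: GeneQuery,
    scoped: ScopedSentence,
    abstract: str,
    params: FinderParams,
    d_cache: Optional[Dict[int, FrozenSet[str]]] = None,
) -> FrozenSet[str]:
    """Predicted concept set for (gene, sentence): G ∩ D, gated on mention."""
    if not has_gene(scoped.sentence.text, gene):
        return frozenset()
    g_set, d_set = candidate_sets(space, scoped, abstract, params, d_cache)
    return intersect_candidates(g_set, d_set, True)


def final_annotation(
    space: SemanticSpace,
    gene_go_set: Iterable[str],
    sentence_text: str,
) -> Optional[Tuple[str, float]]:
    """The member of *gene_go_set* most similar to the sentence.

    Ties broken by ascending accession; None for an empty set.
    """
    members = sorted(gene_go_set)
    if not members:
        return None
    query = embed_text(space, sentence_text)
    vectors = space.concept_vectors
    scored = [(acc, cosine(query, vectors[acc])) for acc in members]
    # same quantized tie rule as top_similar_go
    scored.sort(key=lambda item: (-round(item[1], 12), item[0]))
    return scored[0]


def annotate_document(
    document: Document,
    space: SemanticSpace,
    params: FinderParams = FinderParams(),
    mode: str = "first+fat",
    use_intersection: bool = True,
) -> List[Prediction]:
    """Run the full finder over one document.

    For every scoped sentence and every gene of the document: gate on the
    gene mention, form G (and D unless *use_intersection* is off), and
    emit the top candidate as a :class:`Prediction`.  Deterministic given
    the space and inputs; a document without genes yields no predictions.
    """
    if not document.genes:
        return []
    abstract = abstract_text(document)
    d_cache: Dict[int, FrozenSet[str]] = {}
    queries = [GeneQuery.from_symbol(g) for g in document.genes]
    predictions: List[Prediction] = []
    for scoped in select_scope(document, mode):
        sentence = scoped.sentence
        for query in queries:
            if not has_gene(sentence.text, query):
                continue
            g_set, d_set = candidate_sets(space, scoped, abstract, params, d_cache)
            candidates = intersect_candidates(g_set, d_set, True) \
                if use_intersection else g_set
            chosen = final_annotation(space, candidates, sentence.text)
            if chosen is None:
                continue
            go_id, score = chosen
            predictions.append(Prediction(
                doc_id=document.doc_id,
                gene=query.raw_symbol,
                sentence_ref=(scoped.passage_index, sentence.index_in_passage),
                go_id=go_id,
                score=score,
                sentence_offset=scoped.passage_offset + sentence.offset,
            ))
    return predictions


def annotate_corpus(
    documents: Sequence[Document],
    space: SemanticSpace,
    params: FinderParams = FinderParams(),
    mode: str = "first+fat",
    use_intersection: bool = True,
) -> List[Prediction]:
    out: List[Prediction] = []
    for doc in documents:
        out.extend(annotate_document(doc, space, params, mode, use_intersection))
        logger.info("document %s: %d predictions so far", doc.doc_id, len(out))
    return out


def document_level_predictions(
    predictions: Iterable[Prediction],
) -> Dict[Tuple[str, str, str], Prediction]:
    """Deduplicate to (doc, gene, go) granularity keeping the max score.

    Evaluation is per document–gene pair, so multiple evidence sentences
    for the same triple collapse to the best-scoring one.
    """
    best: Dict[Tuple[str, str, str], Prediction] = {}
    for pred in predictions:
        key = (pred.doc_id, pred.gene.lower(), pred.go_id)
        if key not in best or pred.score > best[key].score:
            best[key] = pred
    return best
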