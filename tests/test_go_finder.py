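"""Candidate sets, intersection, scoping, per-document annotation."""

import numpy as np
import pytest

from gofinder import (FinderParams, GeneQuery, SpaceConfig, build_space,
                      load_space, parse_obo, save_space, top_similar_go)
from gofinder.bioc_io import Document, Passage, Sentence, abstract_text
from gofinder.go_finder import (Scope, annotate_corpus, annotate_document,
                                candidate_sets, document_level_predictions,
                                final_annotation, gene_go,
                                intersect_candidates, select_scope)


def _doc_for_scope():
    """1 front, 1 abstract (2 sentences), 2 paragraphs (3 sentences each)."""
    def sents(texts):
        return [Sentence(t, 0, i) for i, t in enumerate(texts)]
    return Document("d", [
        Passage("front", sents(["Front title."])),
        Passage("abstract", sents(["Abs one.", "Abs two."])),
        Passage("paragraph", sents(["P1 s1.", "P1 s2.", "P1 s3."])),
        Passage("paragraph", sents(["P2 s1.", "P2 s2.", "P2 s3."])),
    ])


def test_finder_params_defaults_and_validation():
    params = FinderParams()
    assert (params.m_fat, params.m_paragraph, params.n_paragraph,
            params.n_fat) == (9, 2, 15, 75)
    with pytest.raises(ValueError):
        FinderParams(m_fat=0)


@pytest.mark.parametrize("mode,expected_texts", [
    ("first+fat", ["Front title.", "Abs one.", "Abs two.", "P1 s1.", "P2 s1."]),
    ("fat", ["Front title.", "Abs one.", "Abs two."]),
    ("last+fat", ["Front title.", "Abs one.", "Abs two.", "P1 s3.", "P2 s3."]),
    ("first_last+fat", ["Front title.", "Abs one.", "Abs two.",
                        "P1 s1.", "P1 s3.", "P2 s1.", "P2 s3."]),
    ("all+fat", ["Front title.", "Abs one.", "Abs two.",
                 "P1 s1.", "P1 s2.", "P1 s3.", "P2 s1.", "P2 s2.", "P2 s3."]),
    ("paragraph", ["P1 s1.", "P2 s1."]),
])
def test_select_scope_modes(mode, expected_texts):
    scoped = select_scope(_doc_for_scope(), mode)
    assert [s.sentence.text for s in scoped] == expected_texts


def test_select_scope_tags_and_errors():
    scoped = select_scope(_doc_for_scope(), "first+fat")
    scopes = {s.sentence.text: s.scope for s in scoped}
    assert scopes["Front title."] is Scope.FAT
    assert scopes["P1 s1."] is Scope.PARAGRAPH_FIRST
    with pytest.raises(ValueError):
        select_scope(_doc_for_scope(), "bogus")


def test_select_scope_no_paragraphs_equals_fat():
    doc = Document("d", [Passage("front", [Sentence("T.", 0, 0)])])
    assert select_scope(doc, "first+fat") == select_scope(doc, "fat")


def test_select_scope_all_sections_includes_other_types():
    doc = _doc_for_scope()
    doc.passages.append(Passage("fig_caption", [Sentence("Cap.", 0, 0)]))
    texts = [s.sentence.text for s in select_scope(doc, "all_sections")]
    assert "Cap." in texts
    assert len(texts) == 10


def test_worked_example_intersection():
    g = {"g5", "g10"}
    d = {"g4", "g8", "g5", "g2", "g9"}
    assert intersect_candidates(g, d, True) == {"g5"}
    assert intersect_candidates(g, d, False) == frozenset()
    assert intersect_candidates({"g1"}, {"g2"}, True) == frozenset()


def test_candidate_sets_cardinality_and_cache(space, documents):
    doc = documents[0]
    scoped = select_scope(doc, "first+fat")
    abstract = abstract_text(doc)
    params = FinderParams(m_fat=2, n_fat=5, m_paragraph=3, n_paragraph=7)
    cache = {}
    fat = next(s for s in scoped if s.scope is Scope.FAT)
    para = next(s for s in scoped if s.scope is Scope.PARAGRAPH_FIRST)
    g_fat, d_fat = candidate_sets(space, fat, abstract, params, cache)
    g_par, d_par = candidate_sets(space, para, abstract, params, cache)
    assert len(g_fat) == 2 and len(d_fat) == 5
    assert len(g_par) == 3 and len(d_par) == 7
    assert set(cache) == {5, 7}
    assert d_fat == frozenset(a for a, _ in top_similar_go(space, abstract, 5))


def test_candidate_sets_exhaustive_n(space, documents):
    doc = documents[0]
    scoped = select_scope(doc, "fat")[0]
    params = FinderParams(m_fat=1, n_fat=10_000)
    _, d = candidate_sets(space, scoped, abstract_text(doc), params)
    assert d == frozenset(space.ids)


def test_gene_go_requires_mention(space, documents):
    doc = documents[0]
    scoped = select_scope(doc, "fat")[0]
    abstract = abstract_text(doc)
    params = FinderParams(m_fat=3, n_fat=25)
    absent = GeneQuery.from_symbol("NOTPRESENT99")
    assert gene_go(space, absent, scoped, abstract, params) == frozenset()


def test_gene_go_subset_of_g_and_d(space, documents):
    params = FinderParams(m_fat=5, n_fat=20, m_paragraph=3, n_paragraph=10)
    checked = 0
    for doc in documents[:5]:
        abstract = abstract_text(doc)
        cache = {}
        queries = [GeneQuery.from_symbol(g) for g in doc.genes]
        for scoped in select_scope(doc, "first+fat"):
            g_set, d_set = candidate_sets(space, scoped, abstract, params, cache)
            for query in queries:
                out = gene_go(space, query, scoped, abstract, params, cache)
                assert out <= g_set and out <= d_set
                checked += 1
    assert checked > 20


def test_gene_go_monotone_in_m_and_n(space, documents):
    """GeneGO(m,n) ⊆ GeneGO(m',n') for m<=m', n<=n'."""
    grid = [(1, 5), (2, 10), (4, 20), (8, 40)]
    for doc in documents[:4]:
        abstract = abstract_text(doc)
        queries = [GeneQuery.from_symbol(g) for g in doc.genes]
        for scoped in select_scope(doc, "first+fat"):
            for query in queries:
                previous = frozenset()
                for m, n in grid:
                    params = FinderParams(m_fat=m, n_fat=n,
                                          m_paragraph=m, n_paragraph=n)
                    current = gene_go(space, query, scoped, abstract, params)
                    assert previous <= current
                    previous = current


def test_final_annotation(space, ontology):
    assert final_annotation(space, frozenset(), "text") is None
    tid = space.ids[7]
    name = ontology.terms[tid].name
    chosen = final_annotation(space, {tid}, name)
    assert chosen == (tid, pytest.approx(1.0))
    # 3-member argmax against explicit cosine comparison
    members = set(space.ids[10:13])
    sentence = ontology.terms[space.ids[11]].name
    from gofinder import cosine, embed_text
    q = embed_text(space, sentence)
    expected = sorted(((m, cosine(q, space.concept_vectors[m]))
                       for m in sorted(members)),
                      key=lambda item: (-item[1], item[0]))[0]
    assert final_annotation(space, members, sentence) == \
        (expected[0], pytest.approx(expected[1]))


def test_annotate_document_planted(space1000, documents, corpus):
    doc = documents[0]
    preds = annotate_document(doc, space1000,
                              FinderParams(m_fat=1, n_fat=25), "first+fat")
    gold_here = {(g.gene, g.go_id) for g in corpus.gold if g.doc_id == doc.doc_id}
    assert {(p.gene, p.go_id) for p in preds} == gold_here
    for p in preds:
        assert p.doc_id == doc.doc_id and 0.0 < p.score <= 1.0


def test_annotate_document_no_genes(space, documents):
    bare = Document("empty", documents[0].passages, genes=[])
    assert annotate_document(bare, space) == []


def test_emitted_pairs_grow_with_m_fat(space, documents):
    """Doubling m_fat never removes an emitted (gene, sentence) pair."""
    small = FinderParams(m_fat=2, n_fat=25)
    large = FinderParams(m_fat=4, n_fat=25)
    preds_small = annotate_corpus(documents, space, small, "first+fat")
    preds_large = annotate_corpus(documents, space, large, "first+fat")
    pairs_small = {(p.doc_id, p.gene, p.sentence_ref) for p in preds_small}
    pairs_large = {(p.doc_id, p.gene, p.sentence_ref) for p in preds_large}
    assert pairs_small <= pairs_large


def test_pipeline_deterministic_through_archive(space, documents, tmp_path):
    path = str(tmp_path / "space.npz")
    save_space(space, path)
    reloaded = load_space(path)
    params = FinderParams(m_fat=3, n_fat=25)
    assert annotate_corpus(documents, space, params) == \
        annotate_corpus(documents, reloaded, params)


def test_no_intersection_mode_ignores_abstract(space, documents):
    """Without intersection the top sentence concept is emitted directly."""
    params = FinderParams(m_fat=1, n_fat=1)
    with_int = annotate_corpus(documents[:3], space, params)
    without = annotate_corpus(documents[:3], space, params, use_intersection=False)
    assert len(without) >= len(with_int)
    for p in without:
        doc = next(d for d in documents if d.doc_id == p.doc_id)
        passage = doc.passages[p.sentence_ref[0]]
        sentence = passage.sentences[p.sentence_ref[1]]
        top1 = top_similar_go(space, sentence.text,
                              1 if passage.passage_type in
                              ("front", "abstract", "title_2") else 1)[0]
        assert p.go_id == top1[0]


def test_document_level_dedup():
    from gofinder.go_finder import Prediction
    preds = [
        Prediction("d", "ASK1", (0, 0), "GO:1", 0.5),
        Prediction("d", "ask1", (1, 0), "GO:1", 0.9),
        Prediction("d", "ASK1", (1, 1), "GO:2", 0.4),
    ]
    best = document_level_predictions(preds)
    assert set(best) == {("d", "ask1", "GO:1"), ("d", "ask1", "GO:2")}
    assert best[("d", "ask1", "GO:1")].score == 0.9
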