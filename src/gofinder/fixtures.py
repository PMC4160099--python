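"""Synthetic ontologies and BioC corpora with planted gene-function signal.

The generator exists so every pipeline stage is testable without any
download.  It emulates the *structure* the finder relies on — an is_a DAG
of named concepts; articles with front, abstract, title_2 and paragraph
passages; gene mentions co-occurring with concept names; abstracts that
echo the concepts discussed in the body — not the statistics of real
biomedical prose.

Concept names are built from a synthetic consonant-vowel lexicon so that
name token sets are pairwise disjoint *after stemming* (asserted at
generation) and never collide with stop words.  Distractor sentences draw
on lexicon words used by no concept name, so chance similarity between an
unplanted sentence and any concept is near zero and planted-signal tests
are stable.

With ``plant_rate=1`` every eligible sentence (FAT or paragraph-first)
carries exactly one concept name verbatim plus one of the document's gene
symbols, and the abstract echoes that name — the configuration under
which the intersection pipeline with m_fat=1 must recover the plant
perfectly.
"""

from __future__ import annotations

import io
import itertools
import random
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set, Tuple

from .bioc_io import Document, Passage, Sentence, write_bioc
from .evaluation import GoldAnnotation
from .ontology import Ontology, parse_obo
from .text_norm import default_stoplist, generalize_symbol, stem

__all__ = ["FixtureSpec", "ToyOntology", "CorpusFixture",
           "make_toy_ontology", "make_synthetic_corpus"]

_CONSONANTS = "bdfgjklmnprstvz"
_VOWELS = "aiou"  # no 'e' (step-5 e-deletion) and no 'y' (consonant/vowel dual role)

#: Gene symbol pool; generalized forms are distinct and >= 2 letters.
GENE_POOL = ("ASK1", "MAPK8", "TP53", "BRCA2", "CDK5", "EGFR", "NOTCH3", "WNT5A")


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for the synthetic corpus."""

    num_terms: int = 100
    num_docs: int = 20
    sentences_per_paragraph: int = 3
    plant_rate: float = 1.0
    seed: int = 7

    def __post_init__(self) -> None:
        if self.num_terms < 10:
            raise ValueError("num_terms must be >= 10")
        if not 0.0 <= self.plant_rate <= 1.0:
            raise ValueError("plant_rate must be in [0, 1]")


@dataclass
class ToyOntology:
    ontology: Ontology
    obo_text: str


@dataclass
class CorpusFixture:
    documents: List[Document]
    gold: List[GoldAnnotation]

    @property
    def bioc_xml(self) -> bytes:
        buf = io.BytesIO()
        write_bioc(self.documents, buf)
        return buf.getvalue()

    @property
    def gold_tsv(self) -> str:
        return "".join(f"{g.doc_id}\t{g.gene}\t{g.go_id}\n" for g in self.gold)

    @property
    def genes_tsv(self) -> str:
        return "".join(f"{d.doc_id}\t{g}\n" for d in self.documents
                       for g in d.genes)


def _lexicon(rng: random.Random, count: int, *,
             exclude_stems: Set[str], exclude_words: Set[str]) -> List[str]:
    """Deterministic synthetic words with pairwise-distinct Porter stems."""
    stop = default_stoplist()
    words: List[str] = []
    seen_stems = set(exclude_stems)
    syllables = [c + v for c in _CONSONANTS for v in _VOWELS]
    while len(words) < count:
        n_syll = rng.choice((2, 2, 3))
        word = "".join(rng.choice(syllables) for _ in range(n_syll))
        word_stem = stem(word)
        if (word in stop or word in exclude_words or word_stem in seen_stems
                or any(generalize_symbol(g) == word for g in GENE_POOL)):
            continue
        seen_stems.add(word_stem)
        words.append(word)
    return words


def make_toy_ontology(spec: FixtureSpec) -> ToyOntology:
    """A random is_a DAG of ``num_terms`` synthetically named concepts.

    Names have 2–4 tokens; token sets are pairwise disjoint after
    stemming (asserted).  Every term carries a definition and one synonym
    built from extra lexicon words, so all four space content modes have
    material to work with.  Each non-root term has 1–2 parents among
    earlier terms; term 1 is the single root.  Output is deterministic in
    ``spec.seed``: the OBO text is byte-identical across runs.
    """
    rng = random.Random(spec.seed)
    name_words = _lexicon(rng, spec.num_terms * 4,
                          exclude_stems=set(), exclude_words=set())
    extra_words = _lexicon(rng, spec.num_terms + 10,
                           exclude_stems={stem(w) for w in name_words},
                           exclude_words=set(name_words))

    word_iter = iter(name_words)
    stanzas = ["format-version: 1.2\nontology: gofinder-toy\n"]
    all_name_stems: List[Set[str]] = []
    for i in range(1, spec.num_terms + 1):
        tid = f"GO:{i:07d}"
        n_tokens = rng.choice((2, 3, 3, 4))
        tokens = [next(word_iter) for _ in range(n_tokens)]
        name = " ".join(tokens)
        stems = {stem(t) for t in tokens}
        for other in all_name_stems:
            assert not (stems & other), "name token stems must be disjoint"
        all_name_stems.append(stems)
        definition = "A synthetic process of {} involving {} and {}.".format(
            name, rng.choice(extra_words), rng.choice(extra_words))
        synonym = " ".join(reversed(tokens)) + " " + rng.choice(extra_words)
        lines = [f"\n[Term]", f"id: {tid}", f"name: {name}",
                 f'def: "{definition}" []', f'synonym: "{synonym}" EXACT []']
        if i > 1:
            n_parents = 1 if i <= 3 else rng.choice((1, 1, 2))
            parent_pool = list(range(1, i))
            for p in sorted(rng.sample(parent_pool, min(n_parents, len(parent_pool)))):
                lines.append(f"is_a: GO:{p:07d}")
        stanzas.append("\n".join(lines) + "\n")
    obo_text = "".join(stanzas)
    return ToyOntology(ontology=parse_obo(obo_text), obo_text=obo_text)


def _distractor_pool(ontology: Ontology, rng: random.Random, count: int) -> List[str]:
    used_words: Set[str] = set()
    used_stems: Set[str] = set()
    for term in ontology.terms.values():
        for text in (term.name, term.definition, *term.synonyms):
            for token in text.lower().split():
                token = "".join(ch for ch in token if ch.isalnum())
                if token:
                    used_words.add(token)
                    used_stems.add(stem(token))
    return _lexicon(rng, count, exclude_stems=used_stems, exclude_words=used_words)


def make_synthetic_corpus(ontology: Ontology, spec: FixtureSpec) -> CorpusFixture:
    """Documents with planted (gene, concept) signal plus matching gold.

    Per document: 1 front sentence, an abstract of 3 content sentences
    plus 1 echo sentence, 1 title_2 sentence, and 3 paragraphs of
    ``sentences_per_paragraph`` sentences.  Eligible sentences (FAT and
    paragraph-first) are planted with probability ``plant_rate``; the
    echo sentence repeats the names planted outside the abstract so the
    document-level candidate set D can contain them.  The gold TSV lists
    exactly the planted (doc, gene, concept) triples.
    """
    rng = random.Random(spec.seed + 1)
    fillers = _distractor_pool(ontology, rng, 200)
    term_ids = [tid for tid in ontology.retrieval_ids()
                if ontology.terms[tid].name.strip()]

    documents: List[Document] = []
    gold: List[GoldAnnotation] = []
    for d in range(1, spec.num_docs + 1):
        doc_id = f"DOC{d:04d}"
        genes = rng.sample(GENE_POOL, 2)
        plant_terms = iter(rng.sample(term_ids, min(8, len(term_ids))))

        def filler_phrase(k: int) -> str:
            return " ".join(rng.choice(fillers) for _ in range(k))

        planted_here: List[Tuple[str, str]] = []  # (gene, term) per sentence built

        def build_sentence(eligible: bool) -> Tuple[str, str, str]:
            """Return (text, gene, term_id); gene/term empty if unplanted."""
            if eligible and rng.random() < spec.plant_rate:
                term_id = next(plant_terms)
                gene = rng.choice(genes)
                name = ontology.terms[term_id].name
                text = (f"{gene} modulates {name} via "
                        f"{filler_phrase(2)} signalling.")
                return text, gene, term_id
            return f"Observations of {filler_phrase(4)} were recorded.", "", ""

        # Front
        front_text, g, t = build_sentence(True)
        if t:
            planted_here.append((g, t))
            gold.append(GoldAnnotation(doc_id, g, t))
        front = Passage("front", [Sentence(front_text, 0, 0)])

        # Title_2
        title_text, g, t = build_sentence(True)
        if t:
            planted_here.append((g, t))
            gold.append(GoldAnnotation(doc_id, g, t))
        title_2 = Passage("title_2", [Sentence(title_text, 0, 0)])

        # Paragraphs: only the first sentence is eligible
        paragraphs: List[Passage] = []
        for _ in range(3):
            sents: List[Sentence] = []
            for si in range(spec.sentences_per_paragraph):
                text, g, t = build_sentence(si == 0)
                if t:
                    planted_here.append((g, t))
                    gold.append(GoldAnnotation(doc_id, g, t))
                sents.append(Sentence(text, 0, si))
            paragraphs.append(Passage("paragraph", sents))

        # Abstract: 3 eligible content sentences + 1 echo of body plants
        abs_sents: List[Sentence] = []
        for si in range(3):
            text, g, t = build_sentence(True)
            if t:
                gold.append(GoldAnnotation(doc_id, g, t))
            abs_sents.append(Sentence(text, 0, si))
        echoed = [ontology.terms[t].name for _, t in planted_here]
        if echoed:
            echo_text = "This article also discusses " + ", ".join(echoed) + "."
        else:
            echo_text = f"Further notes on {filler_phrase(3)} follow."
        abs_sents.append(Sentence(echo_text, 0, 3))
        abstract = Passage("abstract", abs_sents)

        passages = [front, abstract, title_2] + paragraphs
        _assign_offsets(passages)
        documents.append(Document(doc_id=doc_id, passages=passages, genes=genes))

    return CorpusFixture(documents=documents, gold=gold)


def _assign_offsets(passages: List[Passage]) -> None:
    """Document-level passage offsets, passage-relative sentence offsets."""
    cursor = 0
    for passage in passages:
        passage.offset = cursor
        rel = 0
        sents = []
        for i, s in enumerate(passage.sentences):
            sents.append(Sentence(text=s.text, offset=rel, index_in_passage=i))
            rel += len(s.text) + 1
        passage.sentences = sents
        cursor += rel
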