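"""Shared fixtures: synthetic ontology/corpus and an independent ranking oracle."""

import hashlib

import numpy as np
import pytest

from gofinder import (FixtureSpec, SpaceConfig, build_space, make_synthetic_corpus,
                      make_toy_ontology, parse_obo, read_bioc)
from gofinder.text_norm import default_stoplist, normalize_text

FIXTURE_SPEC = FixtureSpec(num_terms=100, num_docs=20,
                           sentences_per_paragraph=3, plant_rate=1.0, seed=7)

#: Space size used for planted-signal runs: large enough that random index
#: vectors are near-orthogonal (pairwise cosine sd ~ 0.03) and chance
#: retrieval is negligible against a 100-concept vocabulary.
PLANTED_DIM = 1000

CHAIN_OBO = """format-version: 1.2
ontology: chain-toy

[Term]
id: GO:0000003
name: root process

[Term]
id: GO:0000002
name: middle process
is_a: GO:0000003

[Term]
id: GO:0000001
name: leaf process
is_a: GO:0000002
"""


@pytest.fixture(scope="session")
def toy():
    return make_toy_ontology(FIXTURE_SPEC)


@pytest.fixture(scope="session")
def ontology(toy):
    return toy.ontology


@pytest.fixture(scope="session")
def corpus(ontology):
    return make_synthetic_corpus(ontology, FIXTURE_SPEC)


@pytest.fixture(scope="session")
def documents(corpus):
    return read_bioc(corpus.bioc_xml)


@pytest.fixture(scope="session")
def space(ontology):
    """Default-config space (dimension 200, nonzeros 10, seed '1234')."""
    return build_space(ontology, SpaceConfig())


@pytest.fixture(scope="session")
def space1000(ontology):
    """Near-orthogonal space for planted-signal checks."""
    return build_space(ontology, SpaceConfig(dimension=PLANTED_DIM))


@pytest.fixture(scope="session")
def chain_ontology():
    """GO:0000001 is_a GO:0000002 is_a GO:0000003."""
    return parse_obo(CHAIN_OBO)


# ---------------------------------------------------------------------------
# Independent oracle: re-derives token index vectors straight from the
# declared hashing contract (SHA-256 of seed||NUL||token seeding a PCG
# generator) and ranks concepts with an explicit python sort.  It shares
# no code path with gofinder.semantic_space beyond numpy's RNG.
# ---------------------------------------------------------------------------

def oracle_token_vector(config: SpaceConfig, token: str) -> np.ndarray:
    digest = hashlib.sha256((config.seed + "\x00" + token).encode()).digest()
    rng = np.random.default_rng(int.from_bytes(digest[:8], "big"))
    coords = rng.choice(config.dimension, size=config.nonzeros, replace=False)
    v = np.zeros(config.dimension)
    for c in coords[: config.nonzeros // 2]:
        v[c] += 1.0
    for c in coords[config.nonzeros // 2:]:
        v[c] -= 1.0
    return v


def oracle_embed(config: SpaceConfig, text: str, stoplist=None) -> np.ndarray:
    tokens = normalize_text(text, default_stoplist() if stoplist is None else stoplist)
    v = np.zeros(config.dimension)
    for t in tokens:
        v = v + oracle_token_vector(config, t)
    norm = float(np.sqrt(np.sum(v * v)))
    return v / norm if norm > 0 else v


def oracle_rank(space, query: str):
    """All (accession, cosine) pairs: descending cosine, ascending id."""
    q = oracle_embed(space.config, query, space.stoplist)
    scored = []
    for i, acc in enumerate(space.ids):
        row = space.matrix[i]
        denom = float(np.sqrt(np.sum(q * q)) * np.sqrt(np.sum(row * row)))
        sim = float(np.dot(q, row) / denom) if denom > 0 else 0.0
        scored.append((acc, sim))
    # descending similarity quantized to 12 decimals, ascending accession —
    # the declared tie rule
    return sorted(scored, key=lambda item: (-round(item[1], 12), item[0]))


@pytest.fixture(scope="session")
def brute_force_rank():
    return oracle_rank
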