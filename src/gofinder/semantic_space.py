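"""Random-indexing semantic vector space over ontology concepts.

Each token receives a sparse ternary *index vector*: ``nonzeros`` distinct
coordinates out of ``dimension``, half set to +1 and half to -1, drawn by a
pseudo-random generator keyed by a stable 64-bit hash of ``seed || token``.
Random index vectors of distinct tokens are near-orthogonal in expectation,
which is what lets their sums act as a linear-complexity surrogate for an
SVD-reduced document-term space.

Each ontology concept is treated as a document: its text (name, optionally
definition and synonyms) is normalized and the concept vector is the sum of
its tokens' index vectors (with multiplicity), scaled to unit norm.  Query
text is embedded through the identical path, so a query equal to a
concept's exact document text attains cosine 1 with that concept.  The
space is open-vocabulary: unknown query tokens still get index vectors,
derived on demand from the seed.

Determinism contract: rebuilding with the same (ontology, config) yields
bit-identical concept vectors on any platform — token hashing uses
SHA-256, never the language's default string hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .ontology import Ontology
from .text_norm import default_stoplist, normalize_text

logger = logging.getLogger(__name__)

__all__ = [
    "CONTENT_MODES",
    "SpaceConfig",
    "IndexVector",
    "SemanticSpace",
    "token_index_vector",
    "build_space",
    "embed_text",
    "cosine",
    "top_similar_go",
    "save_space",
    "load_space",
]

CONTENT_MODES = ("name_only", "name_def", "name_syn", "name_def_syn")


@dataclass(frozen=True)
class SpaceConfig:
    """Configuration of a random-indexing space.

    dimension: length of all vectors (default 200).
    nonzeros:  number of ±1 entries per token index vector; must be even
               (balanced +1/-1) and < dimension (default 10).
    seed:      string seed mixed into every token hash (default "1234").
    content_mode: which concept fields form the concept document.
    """

    dimension: int = 200
    nonzeros: int = 10
    seed: str = "1234"
    content_mode: str = "name_only"

    def __post_init__(self) -> None:
        if self.dimension <= 0:
            raise ValueError("dimension must be positive")
        if self.nonzeros <= 0 or self.nonzeros % 2:
            raise ValueError("nonzeros must be a positive even integer")
        if self.nonzeros >= self.dimension:
            raise ValueError("nonzeros must be smaller than dimension")
        if self.content_mode not in CONTENT_MODES:
            raise ValueError(f"content_mode must be one of {CONTENT_MODES}")


@dataclass(frozen=True)
class IndexVector:
    """Sparse ternary token vector: +1 at positions_pos, -1 at positions_neg."""

    positions_pos: frozenset
    positions_neg: frozenset

    def to_dense(self, dimension: int) -> np.ndarray:
        v = np.zeros(dimension)
        v[list(self.positions_pos)] = 1.0
        v[list(self.positions_neg)] = -1.0
        return v


def _token_rng(seed: str, token: str) -> np.random.Generator:
    digest = hashlib.sha256((seed + "\x00" + token).encode("utf-8")).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "big"))


def token_index_vector(config: SpaceConfig, token: str) -> IndexVector:
    """The deterministic sparse index vector of *token* under *config*."""
    if not token:
        raise ValueError("token must be non-empty")
    rng = _token_rng(config.seed, token)
    coords = rng.choice(config.dimension, size=config.nonzeros, replace=False)
    half = config.nonzeros // 2
    return IndexVector(
        positions_pos=frozenset(int(c) for c in coords[:half]),
        positions_neg=frozenset(int(c) for c in coords[half:]),
    )


def _token_dense(config: SpaceConfig, token: str) -> np.ndarray:
    rng = _token_rng(config.seed, token)
    coords = rng.choice(config.dimension, size=config.nonzeros, replace=False)
    half = config.nonzeros // 2
    v = np.zeros(config.dimension)
    v[coords[:half]] += 1.0
    v[coords[half:]] -= 1.0
    return v


def concept_document(term, content_mode: str) -> str:
    """Assemble a concept's document text per *content_mode*."""
    parts = [term.name]
    if content_mode in ("name_def", "name_def_syn"):
        parts.append(term.definition)
    if content_mode in ("name_syn", "name_def_syn"):
        parts.extend(term.synonyms)
    return " ".join(p for p in parts if p)


@dataclass
class SemanticSpace:
    """Concept vectors plus the config needed to re-derive token vectors."""

    config: SpaceConfig
    ids: List[str]
    matrix: np.ndarray  # shape (len(ids), dimension); rows unit-norm or zero
    stoplist: frozenset
    _token_cache: Dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def concept_vectors(self) -> Dict[str, np.ndarray]:
        return {tid: self.matrix[i] for i, tid in enumerate(self.ids)}

    def _token_vector(self, token: str) -> np.ndarray:
        v = self._token_cache.get(token)
        if v is None:
            v = _token_dense(self.config, token)
            self._token_cache[token] = v
        return v


def _embed_tokens(space: SemanticSpace, tokens: Sequence[str]) -> np.ndarray:
    v = np.zeros(space.config.dimension)
    for t in tokens:
        v += space._token_vector(t)
    n = float(np.linalg.norm(v))
    return v / n if n > 0 else v


def build_space(
    ontology: Ontology,
    config: SpaceConfig = SpaceConfig(),
    stoplist: Optional[Set[str]] = None,
) -> SemanticSpace:
    """Build the concept vector space for every non-obsolete term.

    Terms whose normalized document text is empty get the zero vector and
    a warning; they can never appear near the top of a ranking (cosine
    with a zero vector is defined as 0).
    """
    stop = frozenset(default_stoplist() if stoplist is None else stoplist)
    ids = ontology.retrieval_ids()
    space = SemanticSpace(
        config=config,
        ids=ids,
        matrix=np.zeros((len(ids), config.dimension)),
        stoplist=stop,
    )
    for i, tid in enumerate(ids):
        doc = concept_document(ontology.terms[tid], config.content_mode)
        tokens = normalize_text(doc, stop)
        if not tokens:
            logger.warning("term %s: empty document text, zero vector", tid)
            continue
        space.matrix[i] = _embed_tokens(space, tokens)
    return space


def embed_text(space: SemanticSpace, text: str) -> np.ndarray:
    """Embed free text exactly as concept documents are embedded."""
    return _embed_tokens(space, normalize_text(text, space.stoplist))


def cosine(v1: np.ndarray, v2: np.ndarray) -> float:
    """Cosine similarity; 0 whenever either vector has zero norm."""
    n1 = float(np.linalg.norm(v1))
    n2 = float(np.linalg.norm(v2))
    if n1 == 0.0 or n2 == 0.0:
        return 0.0
    return float(np.dot(v1, v2) / (n1 * n2))


def top_similar_go(
    space: SemanticSpace, query: str, k: int
) -> List[Tuple[str, float]]:
    """Top-*k* concepts by cosine to the embedded query.

    Descending similarity, ties broken by ascending accession, so the
    ranking is a total order and top-k1 is always a prefix of top-k2 for
    k1 <= k2.  Returns min(k, #concepts) entries.

    Similarities are quantized to 12 decimals in the sort key (returned
    values are unquantized): cosines are ratios of integer dot products
    over shared norms, so exact ties are common, and quantization keeps
    them ties — ordered by accession — regardless of the last-ulp
    differences between floating-point evaluation orders.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    q = embed_text(space, query)
    sims = space.matrix @ q  # rows are unit-norm or zero, so this is cosine
    order = sorted(range(len(space.ids)),
                   key=lambda i: (-round(sims[i], 12), space.ids[i]))
    return [(space.ids[i], float(sims[i])) for i in order[:k]]


def save_space(space: SemanticSpace, path: str) -> None:
    """Serialize to a single .npz archive; reload is retrieval-bit-exact."""
    meta = {
        "dimension": space.config.dimension,
        "nonzeros": space.config.nonzeros,
        "seed": space.config.seed,
        "content_mode": space.config.content_mode,
        "stoplist_digest": hashlib.sha256(
            "\n".join(sorted(space.stoplist)).encode("utf-8")
        ).hexdigest(),
    }
    np.savez_compressed(
        path,
        meta=np.array(json.dumps(meta)),
        ids=np.array(space.ids),
        matrix=space.matrix,
        stoplist=np.array(sorted(space.stoplist)),
    )


def load_space(path: str) -> SemanticSpace:
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["meta"]))
        stoplist = frozenset(str(w) for w in archive["stoplist"])
        return SemanticSpace(
            config=SpaceConfig(
                dimension=int(meta["dimension"]),
                nonzeros=int(meta["nonzeros"]),
                seed=str(meta["seed"]),
                content_mode=str(meta["content_mode"]),
            ),
            ids=[str(t) for t in archive["ids"]],
            matrix=np.array(archive["matrix"]),
            stoplist=stoplist,
        )
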