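"""Sentence–gene matching ("Sentence Gene Matcher").

Decides whether a sentence mentions a gene, using two tiers of lexical
matching over generalized forms:

1. the raw symbol occurs in the sentence as a whole token
   (case-insensitive; token boundaries are non-alphanumeric runs);
2. the *generalized* symbol (letters only, lowercased — "ASK1" -> "ask")
   equals some sentence token after the same generalization
   ("Ask-1" -> "ask"), provided the generalized symbol has at least two
   letters.  The two-letter guard stops residues like "p" (from "p38")
   matching a large fraction of all sentences; suppressed matches are
   logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .text_norm import generalize_symbol, tokenize

logger = logging.getLogger(__name__)

__all__ = ["GeneQuery", "has_gene"]

MIN_GENERALIZED_LEN = 2


@dataclass(frozen=True)
class GeneQuery:
    """A gene symbol and its generalized (letters-only, lowercase) form."""

    raw_symbol: str
    generalized: str

    @classmethod
    def from_symbol(cls, raw_symbol: str) -> "GeneQuery":
        if not raw_symbol:
            raise ValueError("gene symbol must be non-empty")
        return cls(raw_symbol=raw_symbol, generalized=generalize_symbol(raw_symbol))


def has_gene(sentence_text: str, gene: GeneQuery) -> bool:
    """True iff the sentence mentions *gene* by exact or generalized token."""
    if not gene.raw_symbol:
        raise ValueError("gene symbol must be non-empty")
    tokens = tokenize(sentence_text)
    if gene.raw_symbol.lower() in tokens:
        return True
    g = gene.generalized
    if not g:
        return False
    generalized_hit = any(generalize_symbol(t) == g for t in tokens)
    if generalized_hit and len(g) < MIN_GENERALIZED_LEN:
        logger.debug(
            "suppressed generalized match of %r (generalized %r too short)",
            gene.raw_symbol, g,
        )
        return False
    return generalized_hit and len(g) >= MIN_GENERALIZED_LEN
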