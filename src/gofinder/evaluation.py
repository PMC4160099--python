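"""Exact and hierarchical precision/recall/F-measure.

Exact scoring treats predictions and gold annotations as sets of
(doc_id, gene, go_id) triples and micro-averages.

Hierarchical scoring works per (doc, gene) pair: both the predicted and
the gold concept sets are expanded with all their is_a ancestors before
computing the overlap, so predicting a parent of the correct concept is
partial credit rather than an outright miss:

    hP = |P_exp ∩ G_exp| / |P_exp|,   hR = |P_exp ∩ G_exp| / |G_exp|

micro-averaged by summing numerators and denominators over pairs.  On a
flat ontology (no parents), expansion is the identity — reflexive
closures — and hierarchical equals exact scoring.

Gene symbols are compared case-insensitively; collisions are logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, FrozenSet, IO, Iterable, List, Set, Tuple, Union

from .ontology import Ontology, expand_set

logger = logging.getLogger(__name__)

__all__ = [
    "GoldAnnotation",
    "EvalResult",
    "exact_prf",
    "hierarchical_prf",
    "evaluate",
    "read_gold_tsv",
    "format_report",
]

Triple = Tuple[str, str, str]  # (doc_id, gene lowercased, go_id)


@dataclass(frozen=True)
class GoldAnnotation:
    doc_id: str
    gene: str
    go_id: str


@dataclass
class EvalResult:
    precision: float = 0.0
    recall: float = 0.0
    f_measure: float = 0.0
    h_precision: float = 0.0
    h_recall: float = 0.0
    h_f_measure: float = 0.0
    tp: int = 0
    fp: int = 0
    fn: int = 0


def _f_measure(p: float, r: float) -> float:
    return 2 * p * r / (p + r) if (p + r) > 0 else 0.0


def _canonical(triples: Iterable[Triple]) -> Set[Triple]:
    out: Set[Triple] = set()
    seen_genes: Dict[Tuple[str, str], str] = {}
    for doc, gene, go in triples:
        key = (doc, gene.lower())
        if key in seen_genes and seen_genes[key] != gene:
            logger.warning("gene symbol case collision in %s: %r vs %r",
                           doc, gene, seen_genes[key])
        seen_genes[key] = gene
        out.add((doc, gene.lower(), go))
    return out


def exact_prf(predicted: Iterable[Triple], gold: Iterable[Triple]) -> EvalResult:
    """Micro-averaged exact match over (doc, gene, go) triples.

    Both sets empty counts as perfect agreement (P = R = 1).
    """
    pred = _canonical(predicted)
    gold_set = _canonical(gold)
    tp = len(pred & gold_set)
    fp = len(pred - gold_set)
    fn = len(gold_set - pred)
    if not pred and not gold_set:
        p = r = 1.0
    else:
        p = tp / len(pred) if pred else 0.0
        r = tp / len(gold_set) if gold_set else 0.0
    return EvalResult(precision=p, recall=r, f_measure=_f_measure(p, r),
                      tp=tp, fp=fp, fn=fn)


def _by_pair(triples: Set[Triple]) -> Dict[Tuple[str, str], Set[str]]:
    out: Dict[Tuple[str, str], Set[str]] = {}
    for doc, gene, go in triples:
        out.setdefault((doc, gene), set()).add(go)
    return out


def hierarchical_prf(
    predicted: Iterable[Triple],
    gold: Iterable[Triple],
    ontology: Ontology,
    averaging: str = "micro",
    denominator: str = "standard",
) -> EvalResult:
    """Ancestor-expanded P/R/F per (doc, gene) pair.

    averaging: "micro" (sum numerators/denominators; default) or "macro"
    (mean of per-pair ratios over pairs where they are defined).
    denominator: "standard" (hP over |P_exp|) or "printed", an audit
    variant scoring precision over the gold-side expansion as well.
    """
    if averaging not in ("micro", "macro"):
        raise ValueError("averaging must be 'micro' or 'macro'")
    if denominator not in ("standard", "printed"):
        raise ValueError("denominator must be 'standard' or 'printed'")
    pred_pairs = _by_pair(_canonical(predicted))
    gold_pairs = _by_pair(_canonical(gold))
    p_num = p_den = r_num = r_den = 0
    p_ratios: List[float] = []
    r_ratios: List[float] = []
    for pair in sorted(set(pred_pairs) | set(gold_pairs)):
        p_exp = expand_set(ontology, pred_pairs.get(pair, set()))
        g_exp = expand_set(ontology, gold_pairs.get(pair, set()))
        overlap = len(p_exp & g_exp)
        p_denom = len(g_exp) if denominator == "printed" else len(p_exp)
        if p_denom:
            p_num += overlap
            p_den += p_denom
            p_ratios.append(overlap / p_denom)
        if g_exp:
            r_num += overlap
            r_den += len(g_exp)
            r_ratios.append(overlap / len(g_exp))
    if averaging == "micro":
        hp = p_num / p_den if p_den else 0.0
        hr = r_num / r_den if r_den else 0.0
    else:
        hp = sum(p_ratios) / len(p_ratios) if p_ratios else 0.0
        hr = sum(r_ratios) / len(r_ratios) if r_ratios else 0.0
    return EvalResult(h_precision=hp, h_recall=hr,
                      h_f_measure=_f_measure(hp, hr))


def evaluate(
    predicted: Iterable[Triple],
    gold: Iterable[Triple],
    ontology: Ontology,
    averaging: str = "micro",
) -> EvalResult:
    """Exact and hierarchical scores in one result."""
    predicted = list(predicted)
    gold = list(gold)
    exact = exact_prf(predicted, gold)
    hier = hierarchical_prf(predicted, gold, ontology, averaging=averaging)
    exact.h_precision = hier.h_precision
    exact.h_recall = hier.h_recall
    exact.h_f_measure = hier.h_f_measure
    return exact


def read_gold_tsv(stream: Union[str, IO[str]]) -> List[GoldAnnotation]:
    """Gold file: TSV of doc_id, gene, go_id; '#' comments allowed."""
    text = stream if isinstance(stream, str) else stream.read()
    out: List[GoldAnnotation] = []
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"gold TSV line {lineno}: expected 3 columns")
        out.append(GoldAnnotation(doc_id=fields[0].strip(),
                                  gene=fields[1].strip(),
                                  go_id=fields[2].strip()))
    return out


def format_report(result: EvalResult) -> str:
    """Human-readable two-block summary of exact and hierarchical scores."""
    return (
        "Exact match:        P={0.precision:.3f} R={0.recall:.3f} "
        "F={0.f_measure:.3f} (tp={0.tp} fp={0.fp} fn={0.fn})\n"
        "Hierarchical match: P={0.h_precision:.3f} R={0.h_recall:.3f} "
        "F={0.h_f_measure:.3f}".format(result)
    )
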