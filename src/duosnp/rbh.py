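"""Reciprocal-best-hit (RBH) orthology from precomputed similarity tables.

RBH is the standard ortholog proxy for a pair of gene sets compared
all-against-all in both directions: genes a and b form a pair when b is a's
top-scoring hit in the A->B table and a is b's top-scoring hit in the B->A
table.  This module consumes blast-tabular style hit lists; it never runs
the aligner itself.

Best-hit selection is bitscore-first with a total tie-break
(bitscore desc, evalue asc, identity desc, subject id lex asc), so the
result is deterministic under any permutation of the input rows.  Multiple
HSPs for one query-subject pair are reduced to their max-bitscore row
before selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence

import numpy as np


@dataclass(frozen=True)
class Hit:
    """One row of an outfmt6-style tabular hit list."""

    query: str
    subject: str
    identity_pct: float
    bitscore: float
    evalue: float = 0.0
    length: int = 0
    mismatch: int = 0
    gapopen: int = 0
    qstart: int = 0
    qend: int = 0
    sstart: int = 0
    send: int = 0

    def __post_init__(self):
        if not 0.0 <= self.identity_pct <= 100.0:
            raise ValueError(f"identity {self.identity_pct} outside [0, 100]")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


@dataclass(frozen=True)
class RbhPair:
    gene_a: str
    gene_b: str
    identity_pct: float  # of the a->b best hit
    bitscore: float


def _hit_rank_key(h: Hit):
    # larger is better for bitscore/identity, smaller for evalue/subject id
    return (-h.bitscore, h.evalue, -h.identity_pct, h.subject)


def best_hits(hits: Iterable[Hit], max_evalue: Optional[float] = None) -> Dict[str, Hit]:
    """Map each query to its single best hit from one search direction.

    ``max_evalue`` optionally discards weak hits before selection.
    """
    # reduce multiple HSPs per (query, subject) to the strongest one
    per_pair: Dict[tuple, Hit] = {}
    for h in hits:
        if max_evalue is not None and h.evalue > max_evalue:
            continue
        key = (h.query, h.subject)
        cur = per_pair.get(key)
        if cur is None or _hit_rank_key(h) < _hit_rank_key(cur):
            per_pair[key] = h
    best: Dict[str, Hit] = {}
    for h in per_pair.values():
        cur = best.get(h.query)
        if cur is None or _hit_rank_key(h) < _hit_rank_key(cur):
            best[h.query] = h
    return best


def reciprocal_pairs(
    map_ab: Dict[str, Hit], map_ba: Dict[str, Hit]
) -> list:
    """Mutual best hits between the two directions, sorted by gene_a.

    Each gene appears in at most one pair; identity/bitscore are taken from
    the A->B best hit.
    """
    pairs = []
    for a, hit_ab in map_ab.items():
        b = hit_ab.subject
        hit_ba = map_ba.get(b)
        if hit_ba is not None and hit_ba.subject == a:
            pairs.append(RbhPair(gene_a=a, gene_b=b,
                                 identity_pct=hit_ab.identity_pct,
                                 bitscore=hit_ab.bitscore))
    pairs.sort(key=lambda p: p.gene_a)
    return pairs


def identity_summary(
    pairs: Sequence[RbhPair], subsets: Dict[str, Sequence[str]]
) -> Dict[str, dict]:
    """Per-subset identity statistics over the gene_a side of the pairs.

    Each subset is a named list of gene_a ids (e.g. literature-derived trait
    classes: HSP, HSF, flowering, seed size, architecture, domestication).
    Genes without an RBH partner are counted as unmatched and excluded from
    the statistics.
    """
    by_a = {p.gene_a: p for p in pairs}
    out: Dict[str, dict] = {}
    for name, genes in subsets.items():
        matched = [by_a[g].identity_pct for g in genes if g in by_a]
        unmatched = [g for g in genes if g not in by_a]
        if matched:
            arr = np.asarray(matched, dtype=float)
            q1, med, q3 = np.percentile(arr, [25, 50, 75])
            stats = {
                "n_matched": len(matched),
                "n_unmatched": len(unmatched),
                "mean": float(arr.mean()),
                "median": float(med),
                "q1": float(q1),
                "q3": float(q3),
            }
        else:
            stats = {"n_matched": 0, "n_unmatched": len(unmatched),
                     "mean": None, "median": None, "q1": None, "q3": None}
        out[name] = stats
    return out
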