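"""Hypergeometric over-representation of a query gene set with Bonferroni
correction.

For a universe of N genes containing a gene set of size K and a query of size
n overlapping it in k genes, the raw p-value is the upper tail
P(X ≥ k) for X ~ Hypergeometric(N, K, n) — equivalently a one-sided Fisher
exact test. Bonferroni multiplies by m, the number of gene sets with a
nonzero intersection with the universe. An optional EASE-style penalisation
(replace k by k−1) is available but off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.stats import hypergeom

from .core_io import GeneSetCollection, normalize_symbol

logger = logging.getLogger("herbnet")

__all__ = ["EnrichmentRow", "hypergeom_upper", "enrich", "top_rows"]


@dataclass(frozen=True)
class EnrichmentRow:
    set_id: str
    set_name: str
    overlap_genes: tuple[str, ...]
    k: int  # overlap size
    K: int  # set size within the universe
    n: int  # query size within the universe
    N: int  # universe size
    p_raw: float
    p_bonferroni: float


def hypergeom_upper(k, K, n, N):
    """Upper-tail hypergeometric probability P(X ≥ k), X ~ Hyp(N, K, n).

    Accepts scalars or broadcastable arrays. scipy evaluates the survival
    function stably; bounds are validated (0 ≤ k ≤ min(K, n); K, n ≤ N).
    """
    k_, K_, n_, N_ = (np.asarray(v) for v in (k, K, n, N))
    if np.any(k_ < 0) or np.any(k_ > np.minimum(K_, n_)):
        raise ValueError("k must satisfy 0 <= k <= min(K, n)")
    if np.any(K_ > N_) or np.any(n_ > N_) or np.any(K_ < 0) or np.any(n_ < 0) or np.any(N_ < 0):
        raise ValueError("require 0 <= K, n <= N")
    p = hypergeom.sf(k_ - 1, N_, K_, n_)
    p = np.clip(p, 0.0, 1.0)
    return float(p) if np.isscalar(k) or p.ndim == 0 else p


def enrich(
    query: Iterable[str],
    sets: GeneSetCollection,
    universe: Iterable[str],
    ease: bool = False,
) -> list[EnrichmentRow]:
    """Over-representation of the query in each gene set.

    Query symbols outside the universe are dropped with a logged count; each
    gene set is intersected with the universe before testing. Bonferroni uses
    m = number of sets with nonzero universe intersection. Rows are sorted by
    (corrected p ascending, set_id ascending).
    """
    universe = {normalize_symbol(s) for s in universe}
    if not universe:
        raise ValueError("empty universe")
    query_raw = {normalize_symbol(s) for s in query}
    query_in = query_raw & universe
    dropped = len(query_raw) - len(query_in)
    if dropped:
        logger.info("enrich: dropped %d query symbol(s) outside the universe", dropped)

    n = len(query_in)
    N = len(universe)
    trimmed = [(gs, gs.members & universe) for gs in sets]
    m = sum(1 for _, members in trimmed if members)

    rows: list[EnrichmentRow] = []
    for gs, members in trimmed:
        overlap = sorted(query_in & members)
        k, K = len(overlap), len(members)
        if K == 0:
            continue
        k_eff = max(k - 1, 0) if ease and k > 0 else k
        p_raw = hypergeom_upper(k_eff, K, n, N) if n else 1.0
        rows.append(
            EnrichmentRow(
                set_id=gs.set_id,
                set_name=gs.name,
                overlap_genes=tuple(overlap),
                k=k,
                K=K,
                n=n,
                N=N,
                p_raw=float(p_raw),
                p_bonferroni=float(min(1.0, m * p_raw)),
            )
        )
    rows.sort(key=lambda r: (r.p_bonferroni, r.set_id))
    return rows


def top_rows(rows: list[EnrichmentRow], top: int = 10) -> list[EnrichmentRow]:
    """The ``--top N`` report view (already sorted by corrected p)."""
    return rows[:top]
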