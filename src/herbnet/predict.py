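"""Compound→target likelihood scoring in the drugCIPHER-CS style.

A query compound is scored against every protein in the interaction network
as the Pearson correlation between two vectors aligned to a fixed reference
drug panel:

* the compound's *chemical similarity vector* — Tanimoto similarity of its
  binary fingerprint to each panel drug's fingerprint, and
* the protein's *functional similarity vector* — for each panel drug, the
  summed kernel of shortest-path distances from the protein to that drug's
  known targets.

High concordance between "chemically close to drug i" and "network-close to
drug i's targets" marks the protein as a putative target. Proteins are ranked
per compound (score descending, symbol ascending); constant vectors make the
correlation undefined, which is flagged and ranked last rather than erroring,
so isolated proteins never abort a proteome-wide ranking.

Herb-level profiles aggregate compound scores per protein by maximum and keep
the top k (default 100).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .core_io import CompoundRecord, InteractionNetwork, ReferenceDrug, normalize_symbol

logger = logging.getLogger("herbnet")

__all__ = [
    "KernelSpec",
    "SimilarityVector",
    "TargetPrediction",
    "HerbProfile",
    "OverlapReport",
    "tanimoto",
    "chem_similarity_vector",
    "proximity",
    "functional_similarity_vector",
    "functional_matrix",
    "concordance_score",
    "score_matrix",
    "rank_targets",
    "herb_profile",
    "profile_overlap_matrix",
    "common_targets",
    "overlap_with_drug_targets",
]


@dataclass(frozen=True)
class KernelSpec:
    """Strictly decreasing transform of shortest-path distance, value 1 at 0.

    ``gaussian-of-distance`` is exp(-d^2); ``exponential-of-distance`` is
    exp(-d) (kept as a pluggable alternative — the ranking's sign structure on
    two-point correlations is invariant to the choice of any strictly
    decreasing kernel). Unreachable targets contribute 0.
    """

    kind: str = "gaussian-of-distance"

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian-of-distance", "exponential-of-distance"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")

    def value(self, distance: float) -> float:
        if self.kind == "gaussian-of-distance":
            return math.exp(-(distance**2))
        return math.exp(-distance)


@dataclass
class SimilarityVector:
    """Panel-aligned similarity values for one compound or protein."""

    owner: str
    panel_order: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.panel_order),):
            raise ValueError("values must align with panel_order")


@dataclass(frozen=True)
class TargetPrediction:
    compound_id: str
    protein: str
    score: float | None  # None = undefined (constant vector)
    rank: int


@dataclass
class HerbProfile:
    herb: str
    entries: list[tuple[str, float]]  # (symbol, aggregated score), score desc

    @property
    def symbols(self) -> set[str]:
        return {s for s, _ in self.entries}


@dataclass
class OverlapReport:
    shared: list[str]
    n_overlap: int
    n_putative: int
    percentage: float  # 100 * overlap / putative, 2 decimals


def tanimoto(fp_a: Iterable[int], fp_b: Iterable[int]) -> float:
    """Tanimoto (Jaccard) similarity of two binary fingerprints.

    Two empty fingerprints share no evidence either way; by convention the
    similarity is 0 (logged).
    """
    a, b = set(fp_a), set(fp_b)
    union = len(a | b)
    if union == 0:
        logger.warning("tanimoto: both fingerprints empty; returning 0")
        return 0.0
    return len(a & b) / union


def chem_similarity_vector(
    query: CompoundRecord, panel: Sequence[ReferenceDrug]
) -> SimilarityVector:
    """Tanimoto of the query fingerprint against each panel drug, panel order."""
    if not panel:
        raise ValueError("reference panel is empty")
    return SimilarityVector(
        owner=query.compound_id,
        panel_order=tuple(d.drug_id for d in panel),
        values=np.array([tanimoto(query.fingerprint, d.fingerprint) for d in panel]),
    )


def proximity(
    protein: str,
    drug: ReferenceDrug,
    network: InteractionNetwork,
    kernel: KernelSpec = KernelSpec(),
) -> float:
    """Summed kernel of shortest-path distances from protein to drug targets.

    Unreachable targets and targets absent from the network contribute 0 (the
    latter logged).
    """
    protein = normalize_symbol(protein)
    if protein not in network:
        raise KeyError(f"protein {protein!r} not in network")
    g = network.graph
    total = 0.0
    for t in sorted(drug.targets):
        if t not in g:
            logger.info("proximity: target %s of %s absent from network", t, drug.drug_id)
            continue
        try:
            d = nx.shortest_path_length(g, protein, t)
        except nx.NetworkXNoPath:
            continue
        total += kernel.value(d)
    return total


def functional_similarity_vector(
    protein: str,
    panel: Sequence[ReferenceDrug],
    network: InteractionNetwork,
    kernel: KernelSpec = KernelSpec(),
) -> SimilarityVector:
    """Proximity of the protein to each panel drug's target set, panel order."""
    if not panel:
        raise ValueError("reference panel is empty")
    return SimilarityVector(
        owner=normalize_symbol(protein),
        panel_order=tuple(d.drug_id for d in panel),
        values=np.array([proximity(protein, d, network, kernel) for d in panel]),
    )


def functional_matrix(
    panel: Sequence[ReferenceDrug],
    network: InteractionNetwork,
    kernel: KernelSpec = KernelSpec(),
) -> tuple[list[str], np.ndarray]:
    """Functional similarity of every network protein to every panel drug.

    Returns (sorted node list, nodes × drugs matrix). Computed with one BFS
    per drug target, so the cost is O(Σ|targets| · |E|).
    """
    g = network.graph
    nodes = sorted(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    F = np.zeros((len(nodes), len(panel)))
    for j, drug in enumerate(panel):
        for t in sorted(drug.targets):
            if t not in g:
                logger.info(
                    "functional_matrix: target %s of %s absent from network", t, drug.drug_id
                )
                continue
            for node, d in nx.single_source_shortest_path_length(g, t).items():
                F[index[node], j] += kernel.value(d)
    return nodes, F


def concordance_score(
    chem_vec: SimilarityVector | np.ndarray, func_vec: SimilarityVector | np.ndarray
) -> float | None:
    """Pearson correlation of the two panel-aligned vectors.

    Returns None (undefined) if either vector is constant; raises for
    vectors shorter than 2 where the correlation does not exist.
    """
    x = chem_vec.values if isinstance(chem_vec, SimilarityVector) else np.asarray(chem_vec, float)
    y = func_vec.values if isinstance(func_vec, SimilarityVector) else np.asarray(func_vec, float)
    if x.shape != y.shape:
        raise ValueError("vector lengths differ")
    if x.size < 2:
        raise ValueError("correlation needs vectors of length >= 2")
    xc, yc = x - x.mean(), y - y.mean()
    nx_, ny_ = np.linalg.norm(xc), np.linalg.norm(yc)
    if nx_ == 0.0 or ny_ == 0.0:
        return None
    return float(np.clip(xc @ yc / (nx_ * ny_), -1.0, 1.0))


def score_matrix(
    compounds: Sequence[CompoundRecord],
    panel: Sequence[ReferenceDrug],
    network: InteractionNetwork,
    kernel: KernelSpec = KernelSpec(),
) -> tuple[list[str], dict[str, np.ndarray]]:
    """Concordance scores of every compound against every network protein.

    Returns the sorted node list and, per compound, a score vector aligned to
    it with NaN marking undefined correlations. Vectorised equivalent of
    calling :func:`concordance_score` node by node.
    """
    if len(panel) < 2:
        raise ValueError("correlation-based scoring needs a panel of >= 2 drugs")
    nodes, F = functional_matrix(panel, network, kernel)
    Fc = F - F.mean(axis=1, keepdims=True)
    Fn = np.linalg.norm(Fc, axis=1)
    scores: dict[str, np.ndarray] = {}
    for comp in compounds:
        c = chem_similarity_vector(comp, panel).values
        cc = c - c.mean()
        cn = np.linalg.norm(cc)
        with np.errstate(invalid="ignore", divide="ignore"):
            s = (Fc @ cc) / (Fn * cn)
        s = np.clip(s, -1.0, 1.0)
        s[(Fn == 0.0) | (cn == 0.0)] = np.nan
        scores[comp.compound_id] = s
    return nodes, scores


def _ranked(nodes: Sequence[str], score_vec: np.ndarray, compound_id: str) -> list[TargetPrediction]:
    # undefined (NaN) last, then score desc, then symbol asc; scores are
    # rounded to 1e-12 in the sort key only, so exact mathematical ties are
    # broken by symbol rather than by floating-point noise
    order = sorted(
        range(len(nodes)),
        key=lambda i: (
            np.isnan(score_vec[i]),
            -round(score_vec[i], 12) if not np.isnan(score_vec[i]) else 0.0,
            nodes[i],
        ),
    )
    return [
        TargetPrediction(
            compound_id=compound_id,
            protein=nodes[i],
            score=None if np.isnan(score_vec[i]) else float(score_vec[i]),
            rank=r + 1,
        )
        for r, i in enumerate(order)
    ]


def rank_targets(
    compound: CompoundRecord,
    panel: Sequence[ReferenceDrug],
    network: InteractionNetwork,
    kernel: KernelSpec = KernelSpec(),
) -> list[TargetPrediction]:
    """Complete putative-target ranking of all network proteins for one compound."""
    nodes, scores = score_matrix([compound], panel, network, kernel)
    return _ranked(nodes, scores[compound.compound_id], compound.compound_id)


def herb_profile(
    herb: str,
    compounds: Sequence[CompoundRecord],
    nodes: Sequence[str],
    scores: Mapping[str, np.ndarray],
    k: int = 100,
) -> HerbProfile:
    """Top-k herb target profile, aggregating compound scores per protein by max.

    Proteins whose score is undefined for every member compound are excluded.
    """
    members = [c for c in compounds if c.herb == herb]
    if not members:
        raise ValueError(f"herb {herb!r} has no compounds")
    agg = np.full(len(nodes), np.nan)
    for c in members:
        agg = np.fmax(agg, scores[c.compound_id])
    defined = ~np.isnan(agg)
    order = sorted(
        (i for i in range(len(nodes)) if defined[i]),
        key=lambda i: (-agg[i], nodes[i]),
    )
    entries = [(nodes[i], float(agg[i])) for i in order[:k]]
    return HerbProfile(herb=herb, entries=entries)


def profile_overlap_matrix(profiles: Sequence[HerbProfile]) -> pd.DataFrame:
    """Symmetric herb × herb matrix of shared profile symbols (diagonal = size)."""
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    names = [p.herb for p in profiles]
    mat = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for a in profiles:
        for b in profiles:
            mat.loc[a.herb, b.herb] = len(a.symbols & b.symbols)
    return mat


def common_targets(profiles: Sequence[HerbProfile]) -> set[str]:
    """Symbols present in every profile."""
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    out = set(profiles[0].symbols)
    for p in profiles[1:]:
        out &= p.symbols
    return out


def overlap_with_drug_targets(
    putative: Iterable[str], reference: Iterable[str]
) -> OverlapReport:
    """Overlap of a putative target set with a reference symbol set.

    The percentage is 100 × |overlap| / |putative| rounded to 2 decimals.
    """
    putative = {normalize_symbol(s) for s in putative}
    reference = {normalize_symbol(s) for s in reference}
    shared = sorted(putative & reference)
    pct = round(100.0 * len(shared) / len(putative), 2) if putative else 0.0
    return OverlapReport(
        shared=shared,
        n_overlap=len(shared),
        n_putative=len(putative),
        percentage=pct,
    )
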