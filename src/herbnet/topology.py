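"""Target-network construction and topological hub screening.

The screening cascade mirrors standard network-pharmacology practice:

1. induce the merged PPI on putative ∪ known disease targets (isolated
   members are kept as degree-0 nodes),
2. *hubs* = nodes whose degree strictly exceeds twice the median degree of
   all nodes in that network,
3. build the subnetwork of direct interactions among hubs, recompute four
   features there (degree, betweenness, closeness, k-core index) and call a
   hub *major* if it strictly exceeds the median of every feature,
4. *candidate targets* = major hubs ∩ putative targets.

Normalisation choices (betweenness scaled to [0,1] per connected component,
Wasserman–Faust closeness reported ×100) do not affect the screen: medians of
a feature are compared against the same feature, so any strictly increasing
per-feature rescaling leaves the hub and major-hub sets unchanged.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .core_io import InteractionNetwork, KnownTargetSet, normalize_symbol

logger = logging.getLogger("herbnet")

__all__ = [
    "TopologyRecord",
    "ScreenResult",
    "FEATURES",
    "build_target_network",
    "topology",
    "topology_frame",
    "median",
    "select_hubs",
    "hubs_from_degrees",
    "hub_subnetwork",
    "screen_major_hubs",
    "major_hubs_from_features",
    "candidate_targets",
    "screen_targets",
]

FEATURES = ("degree", "betweenness", "closeness", "kcore")


@dataclass(frozen=True)
class TopologyRecord:
    """The four per-node screening features.

    ``kcore`` is the node's k-core index ("K value"): the largest k such that
    the node survives recursive deletion of vertices of degree < k.
    """

    node: str
    degree: int
    betweenness: float
    closeness: float  # Wasserman–Faust corrected, reported ×100
    kcore: int


@dataclass
class ScreenResult:
    hub_threshold: float  # 2 × median degree of the screened network
    feature_medians: dict[str, float]  # medians of the four features over hubs
    hubs: set[str]
    major_hubs: set[str]
    candidates: set[str]


def build_target_network(
    putative: Iterable[str], known: KnownTargetSet | Iterable[str], ppi: InteractionNetwork
) -> InteractionNetwork:
    """Induced subgraph of the merged PPI on putative ∪ known target symbols.

    Members absent from the PPI are retained as isolated (degree-0) nodes,
    with a logged count; they can never become hubs under the strict degree
    threshold.
    """
    known_members = known.members if isinstance(known, KnownTargetSet) else set(known)
    union = {normalize_symbol(s) for s in putative} | {
        normalize_symbol(s) for s in known_members
    }
    if not union:
        raise ValueError("putative ∪ known is empty")
    net = ppi.induced(union)
    missing = union - net.nodes
    for sym in sorted(missing):
        net.add_node(sym)
    if missing:
        logger.info(
            "build_target_network: %d member(s) absent from PPI kept as isolated nodes",
            len(missing),
        )
    return net


def topology(network: InteractionNetwork) -> list[TopologyRecord]:
    """Degree, betweenness, closeness and k-core index for every node.

    Betweenness is shortest-path betweenness normalised by (n−1)(n−2)/2
    within each connected component; closeness is the Wasserman–Faust
    reachable-set-corrected closeness, reported ×100; the k-core index comes
    from recursive peeling of vertices of degree < k.
    """
    g = network.graph
    if g.number_of_nodes() == 0:
        return []
    betw: dict[str, float] = {}
    for comp in nx.connected_components(g):
        betw.update(nx.betweenness_centrality(g.subgraph(comp), normalized=True))
    close = nx.closeness_centrality(g, wf_improved=True)
    core = nx.core_number(g)
    return [
        TopologyRecord(
            node=n,
            degree=g.degree(n),
            betweenness=betw[n],
            closeness=100.0 * close[n],
            kcore=core[n],
        )
        for n in sorted(g.nodes)
    ]


def topology_frame(records: Sequence[TopologyRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.node, r.degree, r.betweenness, r.closeness, r.kcore) for r in records],
        columns=["node", *FEATURES],
    ).set_index("node")


def median(values: Sequence[float]) -> float:
    """Sample median: middle element (odd n) or mean of the two middle (even n)."""
    if len(values) == 0:
        raise ValueError("median of empty sequence")
    return float(statistics.median(values))


def hubs_from_degrees(degrees: Mapping[str, int]) -> tuple[set[str], float]:
    """Hub rule on a degree table: degree strictly > 2 × median degree."""
    if not degrees:
        raise ValueError("empty degree table")
    threshold = 2.0 * median(list(degrees.values()))
    return {n for n, d in degrees.items() if d > threshold}, threshold


def select_hubs(network: InteractionNetwork) -> tuple[set[str], float]:
    """Hubs of a network: degree strictly more than 2-fold the median degree."""
    return hubs_from_degrees(dict(network.graph.degree()))


def hub_subnetwork(network: InteractionNetwork, hubs: Iterable[str]) -> InteractionNetwork:
    """Network of direct interactions among the hub nodes (induced subgraph)."""
    hubs = {normalize_symbol(h) for h in hubs}
    missing = hubs - network.nodes
    if missing:
        raise ValueError(f"hubs not in network: {sorted(missing)}")
    return network.induced(hubs)


def major_hubs_from_features(features: pd.DataFrame) -> tuple[set[str], dict[str, float]]:
    """Nodes strictly exceeding the median of each of the four features.

    ``features`` is a node-indexed frame with the FEATURES columns (as from
    :func:`topology_frame`). Returns the major-hub set and the medians used.
    """
    medians = {f: median(features[f].tolist()) for f in FEATURES}
    mask = pd.Series(True, index=features.index)
    for f in FEATURES:
        mask &= features[f] > medians[f]
    return set(features.index[mask]), medians


def screen_major_hubs(hub_net: InteractionNetwork) -> tuple[set[str], dict[str, float]]:
    """Recompute the four features on the hub network and apply the median screen."""
    records = topology(hub_net)
    if not records:
        raise ValueError("hub network is empty")
    return major_hubs_from_features(topology_frame(records))


def candidate_targets(major_hubs: Iterable[str], putative: Iterable[str]) -> set[str]:
    """Major hubs that are also putative targets."""
    return {normalize_symbol(s) for s in major_hubs} & {
        normalize_symbol(s) for s in putative
    }


def screen_targets(
    target_network: InteractionNetwork, putative: Iterable[str]
) -> ScreenResult:
    """Full hub → major-hub → candidate cascade on a target network."""
    hubs, threshold = select_hubs(target_network)
    if hubs:
        major, medians = screen_major_hubs(hub_subnetwork(target_network, hubs))
    else:
        major, medians = set(), {f: float("nan") for f in FEATURES}
    cands = candidate_targets(major, putative)
    return ScreenResult(
        hub_threshold=threshold,
        feature_medians=medians,
        hubs=hubs,
        major_hubs=major,
        candidates=cands,
    )
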