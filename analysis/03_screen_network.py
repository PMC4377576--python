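#!/usr/bin/env python
"""Build the target interaction network and screen hubs → major hubs → candidates.

Induces the PPI on putative ∪ known disease targets, computes degree,
betweenness, closeness and k-core index for every node, applies the strict
2×median-degree hub rule, recomputes the four features on the hub subnetwork,
and keeps hubs strictly above all four feature medians; candidates are the
major hubs that are also putative targets.
"""

import argparse
import json
from pathlib import Path

from herbnet import core_io
from herbnet.topology import (
    build_target_network,
    hub_subnetwork,
    screen_targets,
    topology,
    topology_frame,
)

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--results", type=Path, default=Path("results"))
args = parser.parse_args()

inputs = args.results / "inputs"
network = core_io.load_ppi([inputs / "ppi.tsv"])
putative = set(core_io.load_symbol_list(args.results / "putative_targets.txt"))
known = set(core_io.load_symbol_list(inputs / "known_targets.txt"))

target_net = build_target_network(putative, known, network)
records = topology(target_net)
topology_frame(records).to_csv(args.results / "topology.tsv", sep="\t")

screen = screen_targets(target_net, putative)
(args.results / "screen.json").write_text(
    json.dumps(
        {
            "hub_threshold": screen.hub_threshold,
            "feature_medians": screen.feature_medians,
            "hubs": sorted(screen.hubs),
            "major_hubs": sorted(screen.major_hubs),
            "candidates": sorted(screen.candidates),
        },
        indent=2,
        sort_keys=True,
    )
    + "\n"
)
if screen.hubs:
    core_io.write_graphml(
        hub_subnetwork(target_net, screen.hubs), args.results / "hub_network.graphml"
    )

print(f"target network: {len(target_net)} nodes, {target_net.number_of_edges()} edges")
print(f"hubs (degree > {screen.hub_threshold:g}): {len(screen.hubs)}")
print("feature medians over hubs: "
      + ", ".join(f"{k}={v:.4g}" for k, v in sorted(screen.feature_medians.items())))
print(f"major hubs (strictly above all four medians): {len(screen.major_hubs)}")
print(f"candidate targets (major hubs ∩ putative): {len(screen.candidates)}")
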