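#!/usr/bin/env python
"""Generate the study-scale synthetic input bundle.

Writes a druggable proteome (scale-free PPI), a reference drug panel with
network-localised target modules, five herbs of noisy-fingerprint compounds,
a disease target set half-drawn from the planted modules, and a gene-set
collection with the planted positive control — all under results/inputs/.
"""

import argparse
import dataclasses
from pathlib import Path

from herbnet.synth import PRESETS, generate_bundle, write_bundle

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--preset", default="study_scale", choices=sorted(PRESETS))
parser.add_argument("--seed", type=int, default=7)
parser.add_argument("--results", type=Path, default=Path("results"))
args = parser.parse_args()

config = dataclasses.replace(PRESETS[args.preset], seed=args.seed)
bundle = generate_bundle(config)
paths = write_bundle(bundle, args.results / "inputs")

per_herb = {}
for c in bundle.compounds:
    per_herb[c.herb] = per_herb.get(c.herb, 0) + 1
print(f"proteome: {len(bundle.network)} proteins, {bundle.network.number_of_edges()} interactions")
print(f"panel: {len(bundle.panel)} drugs x {config.targets_per_drug} targets")
print("herbs: " + ", ".join(f"{h}={n}" for h, n in sorted(per_herb.items()))
      + f" (total {len(bundle.compounds)})")
print(f"disease targets: {len(bundle.known_targets)}")
print(f"gene sets: {len(bundle.gene_sets)} (incl. PLANTED_DISEASE control)")
print(f"inputs written under {paths['ppi'].parent}")
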