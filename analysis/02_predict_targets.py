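#!/usr/bin/env python
"""Rank putative targets for every compound and build herb target profiles.

Reads results/inputs/, scores all proteins per compound (concordance of
chemical similarity and network proximity against the drug panel), writes
per-herb top-100 profiles and their pairwise overlap matrix, and reports the
overlap of the putative target space with the known disease targets.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from herbnet import core_io
from herbnet.predict import (
    herb_profile,
    overlap_with_drug_targets,
    profile_overlap_matrix,
    common_targets,
    score_matrix,
)

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--results", type=Path, default=Path("results"))
parser.add_argument("--top-k", type=int, default=100)
args = parser.parse_args()

inputs = args.results / "inputs"
config = json.loads((inputs / "config.json").read_text())
fp_len = config["fingerprint_length"]

network = core_io.load_ppi([inputs / "ppi.tsv"])
compounds, summary = core_io.load_compound_catalogue(inputs / "compounds.tsv", fp_len)
panel = core_io.load_panel(inputs / "panel.tsv", fp_len)
known = set(core_io.load_symbol_list(inputs / "known_targets.txt"))

nodes, scores = score_matrix(compounds, panel, network)
herbs = sorted({c.herb for c in compounds})
profiles = [herb_profile(h, compounds, nodes, scores, k=args.top_k) for h in herbs]

outdir = args.results / "profiles"
outdir.mkdir(parents=True, exist_ok=True)
for p in profiles:
    with open(outdir / f"{p.herb}.tsv", "w") as fh:
        fh.write("symbol\tscore\n")
        for sym, sc in p.entries:
            fh.write(f"{sym}\t{sc:.6f}\n")

overlaps = profile_overlap_matrix(profiles)
overlaps.to_csv(args.results / "profile_overlaps.tsv", sep="\t")

defined = np.zeros(len(nodes), dtype=bool)
for vec in scores.values():
    defined |= ~np.isnan(vec)
putative = sorted(nodes[i] for i in range(len(nodes)) if defined[i])
core_io.write_symbol_list(putative, args.results / "putative_targets.txt")
report = overlap_with_drug_targets(putative, known)

print(f"scored {summary['total']} compounds against {len(nodes)} proteins")
print(f"herb profiles (top {args.top_k}) written under {outdir}")
print("pairwise profile overlaps:")
print(overlaps.to_string())
print(f"targets common to all herbs: {len(common_targets(profiles))}")
print(f"putative target space: {len(putative)} proteins; "
      f"{report.n_overlap} ({report.percentage}%) are known disease targets")
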