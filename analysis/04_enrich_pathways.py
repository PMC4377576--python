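#!/usr/bin/env python
"""Hypergeometric pathway enrichment of the candidate targets.

Tests the candidate target set against every gene set (universe = all PPI
proteins), applies Bonferroni correction over the sets with nonzero universe
intersection, and prints the top 10 — the positive control PLANTED_DISEASE
should lead on synthetic runs.
"""

import argparse
import json
from pathlib import Path

from herbnet import core_io
from herbnet.enrich import enrich, top_rows

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--results", type=Path, default=Path("results"))
parser.add_argument("--top", type=int, default=10)
parser.add_argument("--ease", action="store_true", help="apply EASE-style k-1 penalisation")
args = parser.parse_args()

inputs = args.results / "inputs"
network = core_io.load_ppi([inputs / "ppi.tsv"])
gene_sets = core_io.read_gmt(inputs / "gene_sets.gmt")
candidates = set(json.loads((args.results / "screen.json").read_text())["candidates"])

rows = enrich(candidates, gene_sets, network.nodes, ease=args.ease)
with open(args.results / "enrichment.tsv", "w") as fh:
    fh.write("set_id\tset_name\tk\tK\tn\tN\tp_raw\tp_bonferroni\toverlap_genes\n")
    for r in rows:
        fh.write(
            f"{r.set_id}\t{r.set_name}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t"
            f"{r.p_raw:.6g}\t{r.p_bonferroni:.6g}\t{'/'.join(r.overlap_genes)}\n"
        )

print(f"query: {len(candidates)} candidate targets; {len(rows)} testable gene sets")
print(f"top {args.top} (Bonferroni-corrected):")
for r in top_rows(rows, args.top):
    print(f"  {r.set_id:16s} k={r.k:3d}/{r.K:<4d} p={r.p_bonferroni:.3g}  {r.set_name}")
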