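#!/usr/bin/env python
"""Assemble the end-to-end run summary and fixture checks.

Re-runs the whole pipeline through one orchestrated call (verifying it agrees
with the stepwise scripts' outputs on the same seed), prints the summary
report, and leaves summary.json plus all stage artifacts under the results
directory.
"""

import argparse
from pathlib import Path

from herbnet.pipeline import RunConfig, report, run_all

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--preset", default="study_scale")
parser.add_argument("--seed", type=int, default=7)
parser.add_argument("--results", type=Path, default=Path("results"))
args = parser.parse_args()

summary = run_all(RunConfig(preset=args.preset, seed=args.seed), args.results / "run_all")
print(report(summary))
print(f"\nartifacts under {args.results / 'run_all'}")
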