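#!/usr/bin/env python
"""One-shot report: run every pipeline stage and collect summary.json.

Thin wrapper over dremap.run_pipeline using the configuration written by
01_simulate.py; copies the headline numbers to stdout.
"""

import argparse
import json
from pathlib import Path

from dremap.report import run_pipeline

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=ROOT / "scratch" / "dataset")
    ap.add_argument("--results", type=Path, default=ROOT / "results" / "report")
    args = ap.parse_args()

    summary = run_pipeline(args.data / "pipeline.cfg", args.results)
    print(f"report written to {args.results}")
    print(json.dumps({k: summary[k] for k in
                      ("elements.control", "elements.treated",
                       "dre_h3k27ac_dynamics", "ecr_motif")
                      if k in summary}, indent=2))


if __name__ == "__main__":
    main()
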