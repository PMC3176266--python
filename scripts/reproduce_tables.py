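#!/usr/bin/env python
"""Large-scale statistics for a user-supplied target structure.

Runs the full design pipeline many times (default 1000) against one target
with the ViennaRNA backend and reports the mean and standard deviation of
the achieved neutrality and minimum free energy — the protocol behind
published per-target benchmark tables (e.g. miRNA precursor or P5abc
subdomain structures).  The structures themselves are external data and are
not bundled; supply any dot-bracket file.

This takes hours at full scale; use --runs to scale down.

Usage:
  python scripts/reproduce_tables.py --structure target.db \\
      --dg -26.6 --neutrality 0.95 --runs 1000 --out stats.json
"""

import argparse
import json
import statistics
import sys

from rnaforge.backends import get_backend
from rnaforge.cli import _read_structure
from rnaforge.design import AnnealConfig, DesignGoals, design


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--structure", required=True,
                    help="dot-bracket string, file, or '-' for stdin")
    ap.add_argument("--dg", type=float, required=True)
    ap.add_argument("--neutrality", type=float, required=True)
    ap.add_argument("--runs", type=int, default=1000)
    ap.add_argument("--steps", type=int, default=300)
    ap.add_argument("--backend", default="vienna", choices=["vienna", "toy"])
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default=None)
    args = ap.parse_args()

    pt = _read_structure(args.structure)
    goals = DesignGoals(pt, desired_dG=args.dg,
                        desired_neutrality=args.neutrality)
    backend = get_backend(args.backend)
    cfg = AnnealConfig(steps=args.steps, seed=args.seed)
    results = design(goals, args.runs, cfg=cfg, backend=backend)

    etas = [r.neutrality.value for r in results]
    dgs = [r.predicted.dG for r in results]
    stats = {
        "backend": backend.backend_info(),
        "runs": args.runs,
        "desired_dG": args.dg,
        "desired_neutrality": args.neutrality,
        "neutrality_mean": statistics.mean(etas),
        "neutrality_sd": statistics.stdev(etas) if len(etas) > 1 else 0.0,
        "dG_mean": statistics.mean(dgs),
        "dG_sd": statistics.stdev(dgs) if len(dgs) > 1 else 0.0,
    }
    text = json.dumps(stats, indent=2)
    print(text)
    if args.out:
        with open(args.out, "w") as fh:
            fh.write(text)


if __name__ == "__main__":
    sys.exit(main())
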