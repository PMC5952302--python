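#!/usr/bin/env python
"""Full-scale protocol study: 7 protocols x 11 samples at N = 200.

Reproduces the complete study grid (2/60/128/128 s periods, 200-neuron
ring) and the protocol comparisons on C_av and R_av at the end of the
stim-on and stim-off periods.  This is a long computation — hours of CPU
per intensity — and is therefore a standalone script rather than part of
the test suite.

Usage:
    python scripts/full_study.py --K 0.25 --samples 11 --out scratch/full
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

from crstim.batch import BatchSpec, compare_protocols, run_batch
from crstim.params import PROTOCOLS, ExperimentConfig


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--K", type=float, nargs="+", default=[0.25])
    ap.add_argument("--samples", type=int, default=11)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--workers", type=int, default=1)
    ap.add_argument("--out", type=Path, required=True)
    args = ap.parse_args()

    spec = BatchSpec(
        protocols=PROTOCOLS,
        K_values=tuple(args.K),
        sample_ids=tuple(range(1, args.samples + 1)),
        base_config=ExperimentConfig(base_seed=args.seed),
        workers=args.workers,
    )
    summary = run_batch(spec, args.out)

    reports = []
    for K in args.K:
        for proto in PROTOCOLS[1:]:
            for metric in ("C_av_on", "R_av_on", "C_av_off", "R_av_off"):
                reports.append(compare_protocols(
                    summary, (proto, K), ("no_stim", K), metric, side="less"
                ))
    with open(args.out / "comparisons.json", "w") as fh:
        json.dump(reports, fh, indent=2)
    print(f"{len(summary)} runs, {len(reports)} comparisons -> {args.out}")


if __name__ == "__main__":
    main()
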