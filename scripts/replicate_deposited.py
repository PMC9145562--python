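#!/usr/bin/env python
"""Replication runner for a user-supplied morphometric deposit.

Runs the full pipeline (global ANOVA table, per-trait interaction tests,
contrasts, 10-fold cross-validated classifier report, reconstruction,
ordination) on a downloaded specimen table — e.g. the published
three-species *Temnothorax* dataset — and writes the artifacts, with the
ANOVA and cross-validation reports laid out like the published tables.

Usage:
    python scripts/replicate_deposited.py <specimens.csv> \
        --outdir replication [--prescale factor:0.001] [--seed 1]

The deposit is expected as delimited text with a header naming species,
infection status and the 21 trait columns (values in micrometres;
synonym headers accepted).
"""

from __future__ import annotations

import argparse
import sys

from antmorph import RunConfig, run_pipeline
from antmorph.errors import AntmorphError


def main(argv=None) -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("csv", help="path to the downloaded specimen table")
    parser.add_argument("--outdir", default="replication")
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--prescale", default="factor:0.001",
                        help="scale entering the global model "
                             "(factor:<x>, species-z, or none)")
    parser.add_argument("--k", type=int, default=10,
                        help="cross-validation folds")
    parser.add_argument("--epochs", type=int, default=5000,
                        help="neural-network training epochs")
    args = parser.parse_args(argv)

    config = RunConfig(
        outdir=args.outdir, input=args.csv, scenario=None, seed=args.seed,
        prescale=args.prescale, cv_k=args.k, nn_epochs=args.epochs,
    )
    try:
        artifacts = run_pipeline(config)
    except AntmorphError as exc:
        print(f"error: {exc}", file=sys.stderr)
        return 1
    for name, path in artifacts.items():
        print(f"{name}: {path}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
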