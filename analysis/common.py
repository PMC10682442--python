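"""Shared plumbing for the numbered analysis drivers.

Every driver operates on the same staged artifact directory (default
``results/analysis``) so they can be run in order, resumed, or re-run
individually; the configuration is the default synthetic five-subtype
cohort, reproducible from --seed.
"""

from __future__ import annotations

import argparse
import logging

from cernapipe.pipeline import PipelineConfig
from cernapipe.simulate import GeneratorConfig


def parse_args(description: str) -> argparse.Namespace:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--outdir", default="results/analysis")
    args = parser.parse_args()
    logging.basicConfig(level=logging.INFO,
                        format="%(levelname)s %(name)s: %(message)s")
    return args


def pipeline_config(args: argparse.Namespace) -> PipelineConfig:
    return PipelineConfig(outdir=args.outdir, seed=args.seed,
                          generator=GeneratorConfig(seed=args.seed))
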