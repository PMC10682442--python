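#!/usr/bin/env python
"""Split each primary network into shared and subtype-specific parts.

The common network is the edge/node intersection across all five primary
networks; each specific network is its primary network minus the common
edges — the regulatory wiring unique to that subtype.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import parse_args, pipeline_config

from cernapipe.pipeline import run_stage, _slug


def main() -> None:
    args = parse_args(__doc__)
    cfg = pipeline_config(args)
    run_stage(cfg, "network-algebra")
    base = Path(cfg.outdir) / "algebra"
    common = pd.read_csv(base / "common.edges.tsv", sep="\t", comment="#")
    print(f"common network: {len(common)} edges shared by all subtypes")
    for label in cfg.subtype_labels():
        spec = pd.read_csv(base / f"specific_{_slug(label)}.edges.tsv",
                           sep="\t", comment="#")
        print(f"  {label}: {len(spec)} subtype-specific edges")


if __name__ == "__main__":
    main()
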