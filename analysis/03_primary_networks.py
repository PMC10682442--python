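#!/usr/bin/env python
"""Infer each subtype's primary ceRNA network from the filtered expression.

An edge joins two sponge RNAs (mRNA/lncRNA/circRNA) when their expression
is positively correlated (r > 0.4, p < 0.05) and at least one miRNA is
negatively correlated with both; mRNA/lncRNA pairs additionally need
database-validated miRNA interactions, circRNA pairs run correlation-only.
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
    run_stage(cfg, "infer-network")
    for label in cfg.subtype_labels():
        edges = pd.read_csv(
            Path(cfg.outdir) / "networks" / f"primary_{_slug(label)}.edges.tsv",
            sep="\t", comment="#")
        by_evidence = edges["evidence"].value_counts().to_dict() if len(edges) else {}
        print(f"{label}: {len(edges)} edges {by_evidence}")


if __name__ == "__main__":
    main()
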