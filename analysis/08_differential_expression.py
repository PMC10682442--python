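#!/usr/bin/env python
"""Pairwise differential expression of module genes; intersect into biomarkers.

Each subtype's module-gene union is tested against every other subtype
(TMM normalization, conditional NB exact test, BH within comparison);
genes passing FDR < 0.05 and |log2FC| > 0.5 in all four comparisons form
that subtype's biomarker set.
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
    run_stage(cfg, "biomarkers")
    for label in cfg.subtype_labels():
        bio = pd.read_csv(Path(cfg.outdir) / "de" / f"biomarkers_{_slug(label)}.tsv",
                          sep="\t", comment="#")
        print(f"{label}: {len(bio)} biomarkers")
        for _, row in bio.iterrows():
            print(f"    {row['gene']}: avg |log2FC| {row['avg_abs_log2fc']:.2f} "
                  f"(sd {row['std_abs_log2fc']:.2f}), avg FDR {row['avg_fdr']:.2e}")


if __name__ == "__main__":
    main()
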