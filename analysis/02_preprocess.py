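#!/usr/bin/env python
"""Preprocess the cohort: abundance filter, variance filter, outlier removal.

Reports how many genes each pooled filter dropped and which samples the
per-subtype dendrogram cut flagged as outliers.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import parse_args, pipeline_config

from cernapipe.pipeline import run_stage


def main() -> None:
    args = parse_args(__doc__)
    cfg = pipeline_config(args)
    run_stage(cfg, "preprocess")
    rep = pd.read_csv(Path(cfg.outdir) / "preprocess" / "report.tsv",
                      sep="\t", comment="#")
    n_mean = (rep["record"] == "gene_removed_mean").sum()
    n_var = (rep["record"] == "gene_removed_variance").sum()
    print(f"filters removed {n_mean} low-abundance and {n_var} low-variance genes")
    for _, row in rep[rep["record"] == "retained_samples"].iterrows():
        removed = rep[(rep["record"] == "sample_removed")
                      & (rep["subtype"] == row["subtype"])]["value"].tolist()
        print(f"  {row['subtype']}: kept {row['value']} samples, "
              f"removed {len(removed)} outliers {removed}")


if __name__ == "__main__":
    main()
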