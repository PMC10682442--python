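#!/usr/bin/env python
"""Screen module mRNAs for association with overall survival.

For every mRNA in a subtype's retained modules, patients split at the
gene's mean expression (strictly above = high group) and the two groups'
Kaplan-Meier curves are compared with the log-rank test; raw p < 0.05
flags a prognostic candidate.
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
    run_stage(cfg, "survival")
    for label in cfg.subtype_labels():
        res = pd.read_csv(
            Path(cfg.outdir) / "survival" / f"screen_{_slug(label)}.tsv",
            sep="\t", comment="#")
        sig = res[res["significant"]] if len(res) else res
        print(f"{label}: {len(sig)}/{len(res)} module mRNAs with log-rank p < 0.05")
        for _, row in sig.iterrows():
            print(f"    {row['gene']}: chi2 {row['chi_square']:.2f}, "
                  f"p {row['p']:.3g} (high n={row['n_high']}, low n={row['n_low']})")


if __name__ == "__main__":
    main()
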