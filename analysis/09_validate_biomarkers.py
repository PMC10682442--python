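#!/usr/bin/env python
"""Validate each biomarker set with a one-vs-rest SVM under 5-fold CV.

Features are the biomarker genes' expression across all retained samples,
z-scored per training fold; reports per-fold and mean ROC AUC.
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
    run_stage(cfg, "evaluate")
    for label in cfg.subtype_labels():
        path = Path(cfg.outdir) / "evaluate" / f"cv_{_slug(label)}.tsv"
        if not path.exists():
            print(f"{label}: no biomarkers to validate")
            continue
        cv = pd.read_csv(path, sep="\t", comment="#")
        mean = float(cv.loc[cv["fold"] == "mean", "auc"].iloc[0])
        folds = cv.loc[cv["fold"] != "mean", "auc"].astype(float).tolist()
        print(f"{label}: mean AUC {mean:.3f} (folds: "
              + ", ".join(f"{a:.3f}" for a in folds) + ")")


if __name__ == "__main__":
    main()
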