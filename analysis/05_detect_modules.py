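#!/usr/bin/env python
"""Markov-cluster the specific networks and keep lncRNA/circRNA modules.

Each subtype's specific network is partitioned with MCL (inflation 2.0);
only modules containing at least one lncRNA or circRNA — candidate
non-coding regulators — are retained for biomarker work.
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
    run_stage(cfg, "cluster")
    for label in cfg.subtype_labels():
        mods = pd.read_csv(
            Path(cfg.outdir) / "modules" / f"modules_{_slug(label)}.tsv",
            sep="\t", comment="#")
        if not len(mods):
            print(f"{label}: no lncRNA/circRNA modules")
            continue
        n = mods["module"].nunique()
        comp = mods["rna_class"].value_counts().to_dict()
        print(f"{label}: {n} modules over {len(mods)} genes {comp}")


if __name__ == "__main__":
    main()
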