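#!/usr/bin/env python
"""Test each retained module for gene-set over-representation.

Hypergeometric upper-tail test of every (module, gene set) pair against
the post-filter gene universe, Benjamini-Hochberg corrected per subtype;
FDR < 0.05 counts as significant.
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
    run_stage(cfg, "enrich")
    for label in cfg.subtype_labels():
        path = Path(cfg.outdir) / "enrichment" / f"enrichment_{_slug(label)}.tsv"
        res = pd.read_csv(path, sep="\t", comment="#")
        sig = res[res["significant"]] if len(res) else res
        print(f"{label}: {len(sig)}/{len(res)} significant (module, set) pairs")
        for _, row in sig.head(3).iterrows():
            print(f"    {row['module']} x {row['gene_set']}: overlap "
                  f"{row['overlap']}/{row['module_size']}, FDR {row['fdr']:.2e}")


if __name__ == "__main__":
    main()
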