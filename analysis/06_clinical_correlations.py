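"""Correlate cluster gray matter and network topology with clinical scores.

Pearson correlations over patients (NSZ + VSZ) with BH-FDR across the whole
family of (measure, score) pairs.
"""

import pandas as pd

from _common import default_config, parse_args
from morphnet.pipeline import run_pipeline


def main() -> None:
    args = parse_args(__doc__)
    run_pipeline(default_config(args.outdir, args.seed), ["correlate"])
    corr = pd.read_csv(f"{args.outdir}/correlations.tsv", sep="\t")
    print(corr.round(4).to_string(index=False))
    sig = corr[corr["p_adj"] < 0.05]
    print(f"\n{len(sig)}/{len(corr)} correlations significant after FDR")


if __name__ == "__main__":
    main()
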