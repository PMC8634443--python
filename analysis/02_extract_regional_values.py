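"""Extract per-region gray-matter values and the subject x region mean table."""

import pandas as pd

from _common import default_config, parse_args
from morphnet.pipeline import run_pipeline


def main() -> None:
    args = parse_args(__doc__)
    run_pipeline(default_config(args.outdir, args.seed), ["extract"])
    means = pd.read_csv(f"{args.outdir}/region_means.tsv", sep="\t")
    print(f"region means: {means.shape[0]} subjects x {means.shape[1]-1} regions")


if __name__ == "__main__":
    main()
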