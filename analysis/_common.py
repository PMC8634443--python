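"""Shared run configuration for the numbered analysis scripts.

One cohort at the study's group sizes (22 HC / 23 NSZ / 18 VSZ), the full
sparsity grid 0.05-0.39 (step 0.02), and 20 degree-preserving nulls per
small-world normalization (a lighter ensemble than the library default of
100, adequate for the mean-normalization used here).
"""

import argparse

from morphnet.pipeline import RunConfig


def default_config(outdir: str, seed: int) -> RunConfig:
    return RunConfig(outdir=outdir, seed=seed,
                     null_model={"n_null": 20, "n_swaps_per_edge": 10})


def parse_args(description: str) -> argparse.Namespace:
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--outdir", default="results/run")
    ap.add_argument("--seed", type=int, default=1)
    return ap.parse_args()
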