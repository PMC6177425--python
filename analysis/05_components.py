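#!/usr/bin/env python
"""Extract latent axes of prescribing variation.

PCA (SVD of the column-standardized deviance matrix) yields drug loadings
and county projections; leave-class-out refits measure loading stability;
canonical correlation against county demographics (usage-filtered drugs,
collinearity-filtered demographics) tests whether prescribing axes align
with demographic structure.
"""

import argparse
from pathlib import Path

import pandas as pd

from rxvar import pipeline


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results/run"))
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    pipeline.run_pipeline(pipeline.default_config(), args.out, seed=args.seed,
                          stages=["components"])

    vf = pd.read_csv(args.out / "variance_fractions.csv")["variance_fraction"]
    stab = pd.read_csv(args.out / "stability.csv")
    print("variance explained by top 4 components: "
          + ", ".join(f"{v:.1%}" for v in vf.head(4)))
    print(f"leave-class-out stability: {(stab['abs_dot'] > 0.95).mean():.0%} "
          f"of class x component dots above 0.95")
    cca = (args.out / "cca.csv").read_text().splitlines()
    if not cca[0].startswith("#"):
        sig = pd.read_csv(args.out / "cca.csv")
        print(f"CCA: {(sig['p'] < 0.01).sum()} significant dimensions at p<0.01 "
              f"(first correlation {sig['correlation'].iloc[0]:.2f})")


if __name__ == "__main__":
    main()
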