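#!/usr/bin/env python
"""Generate the synthetic claims world at the canonical study conditions.

Writes claims.csv, catalog.csv, counties.csv, adjacency.csv and truth.json
(the planted ground truth) under the run directory. Conditions: 50 counties
in 8 states, 60 drugs in 12 therapeutic classes, 20,000 patients over
2003-2010, two planted latent prescribing components plus per-class and
per-state effects and a county brand preference.
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

    cfg = pipeline.default_config()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    pipeline.run_pipeline(cfg, out, seed=args.seed, stages=["simulate"])

    claims = pd.read_csv(out / "claims.csv")
    catalog = pd.read_csv(out / "catalog.csv")
    print(f"wrote {len(claims):,} first-dispensing claims for "
          f"{claims['person_id'].nunique():,} patients")
    print(f"catalog: {len(catalog)} drugs, "
          f"{catalog['brand_only'].sum()} brand-only, "
          f"{(catalog['classes'].str.count(';') > 0).sum()} multi-class")


if __name__ == "__main__":
    main()
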