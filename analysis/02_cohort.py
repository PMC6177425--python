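#!/usr/bin/env python
"""Build the person-year cohort and per-drug risk sets.

Applies the two-year washout, keeps the female cohort (the default filter),
assigns each person-year to an (age band, year, r, m) bin, and counts
at-risk person-years and first-use events per drug, bin and county, for a
training/holdout split of persons.
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
                          stages=["cohort"])

    py = pd.read_csv(args.out / "person_years.csv")
    rs = pd.read_csv(args.out / "risk_sets.csv")
    print(f"{len(py):,} post-washout person-years "
          f"({py['person_id'].nunique():,} persons), "
          f"{py['bin_id'].nunique():,} observed bins")
    print(f"risk sets: {rs['drug_id'].nunique()} drugs, "
          f"{int(rs['y'].sum()):,} training first-use events")


if __name__ == "__main__":
    main()
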