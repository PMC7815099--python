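#!/usr/bin/env python
"""Exploratory screen: Spearman correlations of every candidate predictor
with motion sickness intensity (SSQ-TS), Bonferroni-corrected over the ten
predictors, written to results/correlations.csv.
"""

import argparse
from pathlib import Path

from vectsick import io as vio
from vectsick import stats


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--features", type=Path, default=Path("results/features.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/correlations.csv"))
    args = ap.parse_args()

    table = vio.read_feature_table(args.features)
    screen = stats.spearman_screen(table)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    screen.table.reset_index().to_csv(args.out, index=False, float_format="%.4f")

    print(f"correlation screen (n={screen.n}, m={screen.m_tests}) -> {args.out}")
    for name, row in screen.table.iterrows():
        print(f"  {name:<18} rho={row['rho']:+.2f}  p={row['p']:.3f}  "
              f"p_adj={row['p_adjusted']:.3f}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
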