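#!/usr/bin/env python
"""Score the raw cohort into the per-participant feature table.

Runs every upstream pipeline stage — SSQ/MSSQ scoring, vection state
classification (FullVection, SDdV), Rotation Likelihoods and Conflict_PB,
OKN desaccading to SPEV, head-movement counting (nHM) — and writes one row
per participant to results/features.csv.
"""

import argparse
from pathlib import Path

from vectsick import io as vio
from vectsick import pipeline


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("scratch/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results/features.csv"))
    args = ap.parse_args()

    table = pipeline.features_from_cohort_dir(args.cohort)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    vio.write_feature_table(table, args.out)

    print(f"feature table ({len(table)} rows) -> {args.out}")
    print(
        "  FullVection mean {:.0f}% (SD {:.0f}); median SPEV {:.1f} deg/s; "
        "median SSQ-TS {:.0f}".format(
            table["full_vection_pct"].mean(),
            table["full_vection_pct"].std(),
            table["spev"].median(),
            table["ssq_ts"].median(),
        )
    )
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
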