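#!/usr/bin/env python
"""Simulate the synthetic 19-participant drum cohort.

Generates raw per-participant data under the stated study conditions —
20-minute exposure to a 60 deg/s optokinetic stimulus, state-switching
vection knob traces, sawtooth OKN eye traces at 220 Hz, low-amplitude head
motion, questionnaires generated from the logit-linear sickness model —
and writes a cohort directory consumable by the scoring stage.

The raw traces are large (tens of MB of CSV), so the default output lives
under scratch/.
"""

import argparse
from pathlib import Path

from vectsick import io as vio
from vectsick import synthetic


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n", type=int, default=19)
    ap.add_argument("--duration", type=float, default=1200.0)
    ap.add_argument("--out", type=Path, default=Path("scratch/cohort"))
    args = ap.parse_args()

    cfg = synthetic.SyntheticCohortConfig(
        n_participants=args.n, seed=args.seed, duration_s=args.duration
    )
    records = synthetic.generate_cohort(cfg)
    vio.write_cohort_dir(records, args.out, config=cfg)

    n_sick = sum(r.sick for r in records)
    n_abort = sum(
        r.fms_series.scores[-1] >= 15 and r.fms_series.times[-1] < 20
        for r in records
    )
    print(f"cohort of {len(records)} written to {args.out}")
    print(f"  {n_sick} participants report being sick; "
          f"{n_abort} hit the FMS stop rule early")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
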