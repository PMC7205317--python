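#!/usr/bin/env python
"""Phase-clustering scenarios: which process can synchronise its targets?

Six in-silico experiments place the peak phases of one process in narrow
windows while the others stay uniform around the clock: (i) control, all
uniform; (ii) transcription windowed at ZT 0/8/16; (iii) degradation;
(iv) deadenylation; (v) polyadenylation; (vi) the empirical mouse-liver
pattern (deadenylases at ZT 2/5/13, polyadenylation at ZT 3.5,
transcription centred at ~ZT 15). Only windowed deadenylation — generic
(iv) or empirical (vi) — imprints distinct clusters on the peak phases of
the L/S ratio and the long-tailed abundance.

Writes results/phase_clustering.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from polya_rhythms.experiments import run_phase_clustering
from polya_rhythms.features import Quantity


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--n", type=int, default=3000, help="sets per scenario")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path,
                    default=Path("results/phase_clustering.csv"))
    args = ap.parse_args()

    rows = []
    for i, sid in enumerate(("i", "ii", "iii", "iv", "v", "vi")):
        for quantity in (Quantity.RATIO, Quantity.LONG):
            res = run_phase_clustering(sid, args.n, args.seed + i,
                                       output_quantity=quantity)
            rows.append({
                "scenario": sid, "output": quantity.value,
                "n_rhythmic": res.n_rhythmic,
                "capture_pm3h": round(res.capture_wide, 3),
                "capture_pm1p5h": round(res.capture_narrow, 3),
                "baseline_pm1p5h": round(res.baseline_narrow, 3),
                "excess_over_baseline": round(res.excess_narrow, 3),
                "ks_uniform_p": f"{res.ks_uniform_p:.2e}",
            })
    table = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, index=False)

    print(table[table.output == "L/S"].to_string(index=False))
    print("\nscenarios iv and vi capture far above baseline (clustered); "
          "ii, iii, v sit at baseline (no clustering)")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
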