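#!/usr/bin/env python
"""Global parameter sweep: phase lags of the outputs behind each process.

Samples the global distributions by Latin hypercube, simulates every set to
its entrained orbit, and summarises how the peak phases of the L/S ratio
(poly(A) length metric) and L (long-tailed abundance) track each input
process. The deadenylation phase is the standout: both outputs sit ~10 h
(circular offset) from the deadenylation peak in a tight band, while the
other processes show diffuse relationships.

Writes results/phase_lags.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from polya_rhythms import Variant, sample_lhs, global_spec
from polya_rhythms.batch import sweep_features
from polya_rhythms.experiments import phase_lag_analysis
from polya_rhythms.features import Quantity


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--n", type=int, default=10_000)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/phase_lags.csv"))
    args = ap.parse_args()

    theta = sample_lhs(global_spec(Variant.FULL), args.n, args.seed)
    df = sweep_features(theta)
    rows = []
    for process in ("trsc", "dgrd", "deA", "polyA"):
        for quantity in (Quantity.RATIO, Quantity.LONG, Quantity.TOTAL):
            for rhythmic_only in (True, False):
                lag = phase_lag_analysis(df, process, quantity,
                                         rhythmic_only=rhythmic_only)
                rows.append({
                    "input_process": process, "output": quantity.value,
                    "rhythmic_only": rhythmic_only, "n": lag.n,
                    "circ_mean_hr": round(lag.circ_mean, 3),
                    "offset_magnitude_hr": round(lag.lag_magnitude, 3),
                    "circ_sd_hr": round(lag.circ_std, 3),
                })
    table = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, index=False)

    dea = table[(table.input_process == "deA") & table.rhythmic_only]
    print(f"swept {args.n} parameter sets (seed {args.seed}); "
          f"{df.attrs['n_failed']} failed solves")
    for _, r in dea.iterrows():
        print(f"  deA -> {r.output}: offset {r.offset_magnitude_hr} h "
              f"(circular SD {r.circ_sd_hr} h, n={r.n})")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
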