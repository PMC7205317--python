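#!/usr/bin/env python
"""Pearson/Spearman versus Sobol indices on circular phase variables.

Peak phases live on a 24-h circle (ZT 0 == ZT 24), so linear and rank
correlations between input and output phases are distorted: the
deadenylation -> L/S phase relationship — a near-deterministic circular
shift, and the strongest dependency in the model by Sobol indices — shows
up as a strong *negative* Pearson/Spearman correlation, a spurious reading.
Variance-based indices are immune because they never assume monotonicity.

Writes results/correlation_comparison.csv.
"""

import argparse
from pathlib import Path

from polya_rhythms import Variant, sample_lhs, global_spec
from polya_rhythms.batch import sweep_features
from polya_rhythms.experiments import correlation_comparison
from polya_rhythms.sobol import run_sobol


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--n", type=int, default=5000)
    ap.add_argument("--sobol-n", type=int, default=1024)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path,
                    default=Path("results/correlation_comparison.csv"))
    args = ap.parse_args()

    df = sweep_features(sample_lhs(global_spec(Variant.FULL), args.n, args.seed))
    sobol = run_sobol(Variant.FULL, N=args.sobol_n, repeats=2, seed=args.seed)
    table = correlation_comparison(df, sobol_table=sobol)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, index=False)

    row = table[(table.parameter == "phi_deA") & (table.output == "phase_ratio")]
    print(table.round(3).to_string(index=False))
    print(f"\nphi_deA vs L/S phase: Pearson r = {row.pearson_r.iloc[0]:.2f} "
          f"(spuriously negative) while Sobol total = "
          f"{row.total_mean.iloc[0]:.2f} (dominant driver)")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
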