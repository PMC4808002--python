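#!/usr/bin/env python
"""Hurst-estimator recovery on exact fractional Gaussian noise: R/S and
DFA means across seeds for H in {0.3, 0.5, 0.7, 0.9}."""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import preictal as p


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-seeds", type=int, default=25)
    ap.add_argument("--n", type=int, default=8192)
    ap.add_argument("--out", type=Path, default=Path("results/estimator_recovery.csv"))
    args = ap.parse_args()

    rng = np.random.default_rng(args.seed)
    rows = []
    for h in (0.3, 0.5, 0.7, 0.9):
        series = [p.gen_fgn(args.n, h, rng=rng) for _ in range(args.n_seeds)]
        for name, est in (("rs", p.rs_hurst), ("dfa", p.dfa_hurst)):
            vals = [est(x).h for x in series]
            rows.append(dict(h_true=h, method=name,
                             mean=np.mean(vals), sd=np.std(vals, ddof=1),
                             bias=np.mean(vals) - h, n_seeds=args.n_seeds))
    df = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out, index=False, float_format="%.4f")
    print(df.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    worst = df.bias.abs().max()
    print(f"\nlargest absolute bias {worst:.3f} "
          f"(both estimators rank the four regimes in the correct order: "
          f"{bool(df.groupby('method')['mean'].apply(lambda s: s.is_monotonic_increasing).all())})")
    print(f"table -> {args.out}")


if __name__ == "__main__":
    main()
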