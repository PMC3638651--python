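#!/usr/bin/env python
"""Desk-scale method comparison on simulated pooling data.

Averages truth-recovery curves (fraction of relevant markers in the top M1)
for the rerank pipeline, the two-sample t, the Mann-Whitney AUC and a grid
of SAM penalizations, over replicated sparse pooling simulations with
8 + 8 pools.  Writes a TSV of the curves and, optionally, a PNG.

Usage:
    python scripts/compare_methods.py --seed 1 --out results/comparison.tsv \
        [--replicates 40] [--plot results/comparison.png]
"""

import argparse
from pathlib import Path

from rerankfs.compare import compare_methods


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--replicates", type=int, default=40)
    ap.add_argument("--max-m1", type=int, default=100)
    ap.add_argument("--out", type=Path, required=True)
    ap.add_argument("--plot", type=Path, default=None)
    args = ap.parse_args()

    result = compare_methods(
        n_replicates=args.replicates, seed=args.seed, max_m1=args.max_m1
    )
    args.out.parent.mkdir(parents=True, exist_ok=True)
    result.curves.to_csv(args.out, sep="\t")
    print(f"wrote mean recovery curves ({result.n_replicates} replicates) to {args.out}")
    head = result.curves.loc[[5, 10, 25, 50]]
    print(head.round(3).to_string())

    if args.plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 4.5))
        sam_cols = [c for c in result.curves if c.startswith("sam")]
        lo = result.curves[sam_cols].min(axis=1)
        hi = result.curves[sam_cols].max(axis=1)
        ax.fill_between(result.curves.index, lo, hi, alpha=0.2, label="SAM ($s_0$ grid)")
        for col, style in (("rerank", "-"), ("t", "--"), ("auc", ":")):
            ax.plot(result.curves.index, result.curves[col], style, label=col)
        ax.set_xlabel("number of selected markers $M_1$")
        ax.set_ylabel("mean recovery proportion")
        ax.legend()
        fig.tight_layout()
        fig.savefig(args.plot, dpi=150)
        print(f"wrote plot to {args.plot}")


if __name__ == "__main__":
    main()
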