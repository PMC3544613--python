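#!/usr/bin/env python
"""Per-population diversity and neutrality tests.

Computes n, h, Hd, pi, k, S and the Tajima's D / Fu & Li's F* statistics
for each population and the pooled sample, with two-tailed p-values from
a neutral coalescent conditioned on the observed segregating sites.
"""

import argparse
from pathlib import Path

import pandas as pd

import promopop as pp


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--sim-dir", type=Path, default=Path("results/sim"))
    parser.add_argument("--out-dir", type=Path, default=Path("results/diversity"))
    parser.add_argument("--reps", type=int, default=1000)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    aln = pp.read_alignment(args.sim_dir / "alignment.fasta")
    pmap = pp.read_population_map(args.sim_dir / "population_map.tsv")
    table = pp.collapse_haplotypes(aln, pmap)

    rows = []
    for i, scope in enumerate([*table.populations, None]):
        stats = pp.diversity_summary(
            table, scope, pvalue_reps=args.reps, seed=args.seed + i
        )
        rows.append(stats.__dict__)
        label = stats.scope
        print(
            f"{label:>6}: n={stats.n:3d} h={stats.h:2d} Hd={stats.Hd:.3f} "
            f"pi={stats.pi:.4f} D={stats.tajima_d:+.3f} (p={stats.p_tajima:.3f}) "
            f"F*={stats.fu_li_f_star:+.3f} (p={stats.p_fu_li:.3f})"
        )
    frame = pd.DataFrame(rows)
    for col in ("Hd", "pi", "k", "tajima_d", "fu_li_f_star"):
        frame[col] = frame[col].round(3)
    frame.to_csv(args.out_dir / "diversity_neutrality.tsv", sep="\t", index=False)
    print(f"wrote {args.out_dir / 'diversity_neutrality.tsv'}")


if __name__ == "__main__":
    main()
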