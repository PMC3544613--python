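#!/usr/bin/env python
"""TFBS scan, conservation classification and permutation enrichment.

Scans every haplotype of the simulated cohort against the motif library,
classifies motif loci as conserved (present in all haplotypes at the
homologous alignment location) or non-conserved, aggregates counts by
functional category, and tests each motif for over-representation on the
consensus sequence with a composition-preserving reshuffling null.
"""

import argparse
from pathlib import Path

import pandas as pd

import promopop as pp
from promopop.motifs import hits_to_frame


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--sim-dir", type=Path, default=Path("results/sim"))
    parser.add_argument("--out-dir", type=Path, default=Path("results/tfbs"))
    parser.add_argument("--reps", type=int, default=10000)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    aln = pp.read_alignment(args.sim_dir / "alignment.fasta")
    pmap = pp.read_population_map(args.sim_dir / "population_map.tsv")
    lib = pp.load_motif_library(args.sim_dir / "motif_library.tsv")
    table = pp.collapse_haplotypes(aln, pmap)

    hits = pp.scan_motifs(table, lib)
    hits_to_frame(hits).to_csv(args.out_dir / "hits.tsv", sep="\t", index=False)
    per_hap = pp.aggregate_categories(hits, lib)
    per_hap.reset_index().rename(columns={"index": "haplotype"}).to_csv(
        args.out_dir / "category_counts.tsv", sep="\t", index=False
    )
    print(
        f"{len(hits)} hits; per-haplotype totals "
        f"{per_hap['total'].min()}-{per_hap['total'].max()}"
    )

    summary = pp.classify_conservation(hits, table.h)
    print(
        f"{len(summary.loci)} motif loci: {summary.n_conserved} conserved "
        f"({100 * summary.conserved_fraction:.0f}%), "
        f"{summary.n_non_conserved} non-conserved"
    )
    summary.category_proportions(lib).to_csv(
        args.out_dir / "conservation_categories.tsv", sep="\t", index=False
    )

    consensus = pp.consensus_sequence(aln)
    rows = []
    for i, motif in enumerate(lib):
        res = pp.permutation_enrichment(
            consensus, motif.motif_id, lib, reps=args.reps, seed=args.seed + i
        )
        rows.append(res.__dict__)
        flag = "*" if res.p <= 0.05 else " "
        print(
            f"  {motif.motif_id:>7} ({motif.category:>9}): observed {res.observed:3d}, "
            f"null {res.null_mean:6.1f} +/- {res.null_sd:4.1f}, p={res.p:.4f} {flag}"
        )
    pd.DataFrame(rows).to_csv(args.out_dir / "enrichment.tsv", sep="\t", index=False)
    print(f"wrote {args.out_dir}")


if __name__ == "__main__":
    main()
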