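#!/usr/bin/env python
"""Collapse accessions to haplotypes and profile variation.

Reads the simulated cohort, collapses it with gaps as a fifth state,
calls polymorphic sites (tandem gaps merged to single indel events),
flags rare sites (<2%, 1-2 accessions), and counts per-haplotype
differences from the frequency-weighted consensus.  Writes the haplotype
count table, site table and consensus-difference profile.
"""

import argparse
from pathlib import Path

import pandas as pd

import promopop as pp


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--sim-dir", type=Path, default=Path("results/sim"))
    parser.add_argument("--out-dir", type=Path, default=Path("results/haplotypes"))
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    aln = pp.read_alignment(args.sim_dir / "alignment.fasta")
    pmap = pp.read_population_map(args.sim_dir / "population_map.tsv")
    table = pp.collapse_haplotypes(aln, pmap)
    print(f"{table.h} haplotypes among {table.n} accessions")

    counts = table.counts.reset_index().rename(columns={"index": "haplotype"})
    counts.to_csv(args.out_dir / "haplotype_counts.tsv", sep="\t", index=False)

    sites = pp.classify_rare_sites(pp.call_polymorphic_sites(aln))
    sites.to_frame().to_csv(args.out_dir / "polymorphic_sites.tsv", sep="\t", index=False)
    print(f"{sites.n_sites} polymorphic units, {sites.n_rare} rare")

    consensus = pp.consensus_sequence(aln)
    diffs = pp.diff_from_consensus(table, consensus)
    pd.Series(diffs, name="differences_from_consensus").rename_axis(
        "haplotype"
    ).to_frame().to_csv(args.out_dir / "consensus_differences.tsv", sep="\t")
    print(
        "differences from consensus range "
        f"{min(diffs.values())}-{max(diffs.values())} units"
    )


if __name__ == "__main__":
    main()
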