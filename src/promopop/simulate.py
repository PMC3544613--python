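"""Synthetic promoter-alignment generator.

Emulates the design of the study this package reanalyses: a ~2 kb promoter
founder sequence, five natural populations of 19-26 accessions split into a
southern (xeric) and a northern (mesic) group, 22 haplotypes with fixed
per-population frequencies, substitution and tandem-indel mutations
(including rare variants carried by 1-2 accessions), and optional planted
motif instances for enrichment power tests.

Indels are simulated as alignment columns shared by all records (gap in
carriers, base elsewhere), so generated data is already aligned.
Substitution positions are drawn without replacement, uniform over
non-indel columns (infinite-sites-like).  All randomness flows from the
single integer seed in :class:`SimulationConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import (
    GAP,
    AlignmentSet,
    HaplotypeTable,
    PopulationMap,
    write_alignment,
    write_population_map,
)
from .errors import InvalidArgument, PlantingError

BASES = "ACGT"

#: Published per-population haplotype count table of the study design:
#: 22 haplotypes x 5 populations, 112 accessions, groups southern (P1, P2)
#: and northern (P3, P4, P5).
STUDY_HAPLOTYPE_COUNTS: dict[str, dict[str, int]] = {
    "P1": {"Hap1": 19, "Hap2": 1},
    "P2": {"Hap3": 6, "Hap4": 4, "Hap5": 7, "Hap6": 4},
    "P3": {"Hap1": 1, "Hap7": 17, "Hap8": 1},
    "P4": {
        "Hap7": 7,
        "Hap9": 1,
        "Hap10": 1,
        "Hap11": 1,
        "Hap12": 12,
        "Hap13": 1,
        "Hap14": 1,
        "Hap15": 1,
        "Hap16": 1,
    },
    "P5": {
        "Hap17": 2,
        "Hap18": 5,
        "Hap19": 4,
        "Hap20": 12,
        "Hap21": 2,
        "Hap22": 1,
    },
}

STUDY_GROUPS: dict[str, str] = {
    "P1": "southern",
    "P2": "southern",
    "P3": "northern",
    "P4": "northern",
    "P5": "northern",
}


@dataclass(frozen=True)
class IndelEvent:
    """A tandem deletion of ``length`` founder bases in ``carriers``."""

    length: int
    carriers: tuple[str, ...]
    start: int | None = None  # drawn from seed when None


@dataclass(frozen=True)
class PlantedMotif:
    iupac: str
    copies: int
    targets: tuple[str, ...]


@dataclass(frozen=True)
class SimulationConfig:
    founder_length: int = 2000
    gc_fraction: float = 0.44
    populations: tuple[tuple[str, str, int], ...] = ()  # (name, group, n)
    haplotype_spec: tuple[tuple[str, tuple[tuple[str, int], ...]], ...] = ()
    n_substitutions_per_haplotype: tuple[int, int] = (2, 30)
    indel_events: tuple[IndelEvent, ...] = ()
    rare_variant_count: int = 0
    planted_motifs: tuple[PlantedMotif, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.founder_length <= 0:
            raise InvalidArgument("founder_length must be positive")
        spec = dict(self.haplotype_spec)
        for name, group, n in self.populations:
            if name not in spec:
                raise InvalidArgument(f"population {name!r} has no haplotype spec")
            total = sum(c for _, c in spec[name])
            if total != n:
                raise InvalidArgument(
                    f"population {name!r}: haplotype counts sum to {total}, "
                    f"expected n_accessions={n}"
                )
        lo, hi = self.n_substitutions_per_haplotype
        if not (0 <= lo <= hi):
            raise InvalidArgument("invalid substitution count range")

    @property
    def haplotype_ids(self) -> list[str]:
        out: list[str] = []
        for _, hap_counts in self.haplotype_spec:
            for hap, _ in hap_counts:
                if hap not in out:
                    out.append(hap)
        return out

    def counts_frame(self) -> pd.DataFrame:
        pops = [name for name, _, _ in self.populations]
        frame = pd.DataFrame(0, index=self.haplotype_ids, columns=pops, dtype=int)
        for pop, hap_counts in self.haplotype_spec:
            for hap, c in hap_counts:
                frame.at[hap, pop] = c
        return frame


def study_config(seed: int = 0, planted_motifs: tuple[PlantedMotif, ...] = ()) -> SimulationConfig:
    """Default configuration emulating the study design.

    2000 bp founder, the published 22-haplotype x 5-population count table,
    2-30 substitutions per haplotype, six tandem indels (2-8 bp) on the
    divergent southern-cluster haplotypes, and 21 rare private variants on
    haplotypes carried by 1-2 accessions.
    """
    populations = tuple(
        (pop, STUDY_GROUPS[pop], sum(STUDY_HAPLOTYPE_COUNTS[pop].values()))
        for pop in ("P1", "P2", "P3", "P4", "P5")
    )
    hap_spec = tuple(
        (pop, tuple(STUDY_HAPLOTYPE_COUNTS[pop].items()))
        for pop in ("P1", "P2", "P3", "P4", "P5")
    )
    indels = (
        IndelEvent(4, ("Hap1", "Hap2")),
        IndelEvent(2, ("Hap3", "Hap4", "Hap5", "Hap6")),
        IndelEvent(8, ("Hap1",)),
        IndelEvent(3, ("Hap5",)),
        IndelEvent(6, ("Hap2", "Hap8")),
        IndelEvent(5, ("Hap6",)),
    )
    return SimulationConfig(
        founder_length=2000,
        gc_fraction=0.44,
        populations=populations,
        haplotype_spec=hap_spec,
        n_substitutions_per_haplotype=(2, 30),
        indel_events=indels,
        rare_variant_count=21,
        planted_motifs=planted_motifs,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def generate_founder_sequence(
    length: int, gc_fraction: float = 0.5, seed: int | np.random.Generator = 0
) -> str:
    """Random gap-free founder with i.i.d. bases at the given GC fraction."""
    if length <= 0:
        raise InvalidArgument("length must be positive")
    if not 0.0 <= gc_fraction <= 1.0:
        raise InvalidArgument("gc_fraction must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    return "".join(rng.choice(list(BASES), size=length, p=p))


@dataclass(frozen=True)
class MutationRecipe:
    substitutions: tuple[tuple[int, str], ...]  # (founder position, new base)
    deletions: tuple[tuple[int, int], ...]  # (start, length), founder coords


def _place_indels(
    config: SimulationConfig, rng: np.random.Generator
) -> list[tuple[int, int, tuple[str, ...]]]:
    """Assign non-overlapping, non-adjacent founder intervals to indels."""
    placed: list[tuple[int, int, tuple[str, ...]]] = []
    occupied: set[int] = set()
    for ev in config.indel_events:
        if ev.length <= 0:
            raise InvalidArgument("indel length must be positive")
        if ev.start is not None:
            start = ev.start
            span = set(range(start - 1, start + ev.length + 1))
            if span & occupied:
                raise InvalidArgument(
                    f"indel at {start} overlaps or abuts a previous indel"
                )
        else:
            for _ in range(1000):
                start = int(rng.integers(0, config.founder_length - ev.length))
                span = set(range(start - 1, start + ev.length + 1))
                if not span & occupied:
                    break
            else:
                raise InvalidArgument("could not place indels without overlap")
        occupied |= set(range(start - 1, start + ev.length + 1))
        placed.append((start, ev.length, ev.carriers))
    return sorted(placed)


def build_recipes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> dict[str, MutationRecipe]:
    """Draw a deterministic mutation recipe per haplotype from the seed.

    One haplotype (the first) is kept identical to the founder only if the
    substitution range allows 0; otherwise each haplotype gets a distinct
    set of substitutions, plus its configured indels, plus extra private
    substitutions on rare haplotypes to realise ``rare_variant_count``.
    """
    rng = rng or np.random.default_rng(config.seed)
    indels = _place_indels(config, rng)
    indel_cols = {
        pos for start, length, _ in indels for pos in range(start, start + length)
    }
    free = np.array(sorted(set(range(config.founder_length)) - indel_cols))
    lo, hi = config.n_substitutions_per_haplotype

    counts = config.counts_frame().sum(axis=1)
    hap_ids = config.haplotype_ids
    # haplotypes carried by 1-2 accessions receive the rare private variants
    rare_haps = [h for h in hap_ids if counts[h] <= 2]
    rare_alloc = {h: 0 for h in hap_ids}
    for i in range(config.rare_variant_count):
        if not rare_haps:
            raise InvalidArgument(
                "rare_variant_count > 0 but no haplotype has <= 2 carriers"
            )
        rare_alloc[rare_haps[i % len(rare_haps)]] += 1

    used: set[int] = set()
    recipes: dict[str, MutationRecipe] = {}
    for hap in hap_ids:
        n_subs = int(rng.integers(lo, hi + 1)) + rare_alloc[hap]
        avail = np.array([p for p in free if p not in used])
        if n_subs > len(avail):
            raise InvalidArgument(
                f"not enough free columns for {n_subs} substitutions on {hap}"
            )
        positions = rng.choice(avail, size=n_subs, replace=False)
        subs = tuple(
            (int(pos), _other_base(rng)) for pos in sorted(positions.tolist())
        )
        used |= {int(p) for p in positions}
        dels = tuple(
            (start, length) for start, length, carriers in indels if hap in carriers
        )
        recipes[hap] = MutationRecipe(subs, dels)
    return recipes


def _other_base(rng: np.random.Generator) -> str:
    return str(rng.choice(list(BASES)))


def apply_recipe(founder: str, recipe: MutationRecipe) -> str:
    """Apply a recipe; deletions become gap columns (alignment length kept)."""
    seq = list(founder)
    del_cols = {
        pos for start, length in recipe.deletions for pos in range(start, start + length)
    }
    for pos, base in recipe.substitutions:
        if pos in del_cols:
            raise InvalidArgument(f"substitution at indel column {pos}")
        if not 0 <= pos < len(seq):
            raise InvalidArgument(f"substitution position {pos} outside founder")
        seq[pos] = base if seq[pos] != base else _flip(seq[pos])
    for pos in del_cols:
        if not 0 <= pos < len(seq):
            raise InvalidArgument(f"deletion column {pos} outside founder")
        seq[pos] = GAP
    return "".join(seq)


def _flip(base: str) -> str:
    # guarantee the substitution actually changes the state
    return {"A": "G", "G": "A", "C": "T", "T": "C"}[base]


def mutate_haplotypes(
    founder: str,
    config: SimulationConfig,
    recipes: dict[str, MutationRecipe] | None = None,
) -> dict[str, str]:
    """Materialise every configured haplotype as an aligned gapped sequence."""
    if GAP in founder or "N" in founder:
        raise InvalidArgument("founder must be gap-free")
    if recipes is None:
        recipes = build_recipes(config)
    for hap in config.haplotype_ids:
        if hap not in recipes:
            raise InvalidArgument(f"haplotype {hap!r} has no mutation recipe")
    _check_indel_overlap(recipes)
    return {hap: apply_recipe(founder, recipes[hap]) for hap in config.haplotype_ids}


def _check_indel_overlap(recipes: dict[str, MutationRecipe]) -> None:
    for hap, recipe in recipes.items():
        spans: list[tuple[int, int]] = sorted(
            (s, s + l) for s, l in recipe.deletions
        )
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise InvalidArgument(f"overlapping indels in recipe for {hap!r}")


def assemble_population_sample(
    haplotypes: dict[str, str], config: SimulationConfig
) -> tuple[AlignmentSet, PopulationMap]:
    """One record per accession, named ``<pop>_<index>``, matching the spec
    counts exactly."""
    records: list[tuple[str, str]] = []
    assignments: list[tuple[str, str, str]] = []
    group_of = {name: group for name, group, _ in config.populations}
    for pop, hap_counts in config.haplotype_spec:
        idx = 1
        for hap, count in hap_counts:
            if hap not in haplotypes:
                raise InvalidArgument(f"unknown haplotype id {hap!r}")
            for _ in range(count):
                acc = f"{pop}_{idx:02d}"
                records.append((acc, haplotypes[hap]))
                assignments.append((acc, pop, group_of[pop]))
                idx += 1
    return AlignmentSet(tuple(records)), PopulationMap(tuple(assignments))


# ---------------------------------------------------------------------------
# motif planting
# ---------------------------------------------------------------------------


def _concrete_from_iupac(iupac: str, rng: np.random.Generator) -> str:
    from .motifs import IUPAC_CODES

    out = []
    for sym in iupac.upper():
        if sym not in IUPAC_CODES:
            raise InvalidArgument(f"illegal IUPAC symbol {sym!r}")
        out.append(str(rng.choice(sorted(IUPAC_CODES[sym]))))
    return "".join(out)


def plant_motifs(
    haplotypes: dict[str, str],
    iupac: str,
    copies: int,
    targets: tuple[str, ...],
    seed: int | np.random.Generator = 0,
) -> dict[str, str]:
    """Write >= ``copies`` concrete instances of the motif into each target
    haplotype at random gap-free, non-overlapping loci.  Non-target
    haplotypes are returned unchanged.
    """
    if copies < 0:
        raise InvalidArgument("copies must be >= 0")
    if copies == 0:
        return dict(haplotypes)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = dict(haplotypes)
    m = len(iupac)
    for hap in targets:
        if hap not in haplotypes:
            raise InvalidArgument(f"unknown target haplotype {hap!r}")
        seq = list(out[hap])
        if m >= len([c for c in seq if c != GAP]):
            raise PlantingError(f"motif longer than ungapped {hap!r}")
        # candidate loci: windows of m consecutive alignment columns with no gap
        candidates = [
            i
            for i in range(len(seq) - m + 1)
            if GAP not in seq[i : i + m]
        ]
        rng.shuffle(candidates)
        placed: list[tuple[int, int]] = []
        for start in candidates:
            if len(placed) == copies:
                break
            if any(start < e and s < start + m for s, e in placed):
                continue
            concrete = _concrete_from_iupac(iupac, rng)
            seq[start : start + m] = list(concrete)
            placed.append((start, start + m))
        if len(placed) < copies:
            raise PlantingError(
                f"only {len(placed)} of {copies} copies fit in {hap!r} "
                f"(gap-free, non-overlapping loci exhausted)"
            )
        out[hap] = "".join(seq)
    return out


# ---------------------------------------------------------------------------
# fixtures and file output
# ---------------------------------------------------------------------------


def build_paper_fixture() -> tuple[HaplotypeTable, PopulationMap]:
    """Count-only haplotype table of the published study design.

    22 haplotypes x 5 populations (112 accessions), groups southern
    (P1, P2) and northern (P3, P4, P5).  Sequences are not part of the
    fixture (the study's sequences live in a public archive); statistics
    that need only counts -- Hd, frequency-based AMOVA -- are exact on it.
    """
    pops = ["P1", "P2", "P3", "P4", "P5"]
    hap_ids = [f"Hap{i}" for i in range(1, 23)]
    counts = pd.DataFrame(0, index=hap_ids, columns=pops, dtype=int)
    for pop, hap_counts in STUDY_HAPLOTYPE_COUNTS.items():
        for hap, c in hap_counts.items():
            counts.at[hap, pop] = c
    assignments: list[tuple[str, str, str]] = []
    for pop in pops:
        n = int(counts[pop].sum())
        for i in range(1, n + 1):
            assignments.append((f"{pop}_{i:02d}", pop, STUDY_GROUPS[pop]))
    return HaplotypeTable(counts), PopulationMap(tuple(assignments))


def simulate_study(
    config: SimulationConfig | None = None, seed: int | None = None
) -> tuple[AlignmentSet, PopulationMap, dict[str, str]]:
    """End-to-end generation: founder -> haplotypes -> accession sample.

    Returns the alignment, the population map, and the haplotype sequences.
    """
    if config is None:
        config = study_config(seed=seed if seed is not None else 0)
    elif seed is not None:
        raise InvalidArgument("pass the seed inside the config or alone, not both")
    rng = np.random.default_rng(config.seed)
    founder = generate_founder_sequence(config.founder_length, config.gc_fraction, rng)
    recipes = build_recipes(config, rng)
    haplotypes = mutate_haplotypes(founder, config, recipes)
    for pm in config.planted_motifs:
        haplotypes = plant_motifs(haplotypes, pm.iupac, pm.copies, pm.targets, rng)
    aln, pmap = assemble_population_sample(haplotypes, config)
    return aln, pmap, haplotypes


DEFAULT_MOTIF_LIBRARY: tuple[tuple[str, str, str, str], ...] = (
    # (motif_id, iupac, tf_name, category) -- a small plausible monocot
    # promoter library spanning the 8 functional categories used in reports
    ("GA1", "TAACAAA", "GAmyb", "GA"),
    ("GA2", "TAACAGA", "GAmyb", "GA"),
    ("DOF1", "AAAG", "Dof", "Dof"),
    ("DOF2", "CTTT", "Dof", "Dof"),
    ("LIGHT1", "GATAAG", "GATA", "light"),
    ("LIGHT2", "CCAATT", "CCAAT-box", "light"),
    ("ABA1", "ACGTGKC", "ABRE-like", "ABA"),
    ("MYB1", "WAACCA", "MYB", "drought"),
    ("MYC1", "CANNTG", "MYC", "drought"),
    ("WRKY1", "TTGACY", "WRKY", "defense"),
    ("FLAV1", "MACCWAMC", "MYB-P", "flavonoid"),
    ("CORE1", "TATAWAW", "TATA-box", "core"),
    ("SUGAR1", "TATCCA", "amylase-box", "sugar"),
)


def write_motif_library(path: str | Path, rows=DEFAULT_MOTIF_LIBRARY) -> None:
    pd.DataFrame(
        list(rows), columns=["motif_id", "iupac", "tf_name", "category"]
    ).to_csv(path, sep="\t", index=False)


def write_simulation(
    out_dir: str | Path,
    config: SimulationConfig | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write alignment FASTA, population map TSV and motif library TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aln, pmap, _ = simulate_study(config, seed)
    paths = {
        "alignment": out / "alignment.fasta",
        "population_map": out / "population_map.tsv",
        "motif_library": out / "motif_library.tsv",
    }
    write_alignment(aln, paths["alignment"])
    write_population_map(pmap, paths["population_map"])
    write_motif_library(paths["motif_library"])
    return paths
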