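"""Aligned-sequence containers, haplotype collapsing, and polymorphic-site calling.

Conventions used throughout:

* Alphabet is ``{A, C, G, T, -, N}``; sequences are upper-cased on read.
* The gap character ``-`` is a *fifth state*: two accessions whose aligned
  sequences differ only by a gap column carry different haplotypes.
* ``N`` is missing data.  It equals only itself for haplotype collapsing
  (conservative, deterministic) and never creates a polymorphic site.
* A *tandem gap* -- a maximal run of gap columns carried by the same set of
  accessions -- is a single insertion/deletion event and is counted as one
  polymorphic-site unit.
* Internal coordinates are 0-based half-open; report output is 1-based
  inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, InvalidArgument, MappingError, ParseError

ALPHABET = frozenset("ACGT-N")
GAP = "-"
#: deterministic tie-break order for consensus calls
STATE_ORDER = "ACGT-"


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignmentSet:
    """Accession-labelled, equal-length gapped sequences."""

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        ids = [rid for rid, _ in self.records]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise AlignmentError(f"duplicate accession id {dup!r}")
        if self.records:
            ref = len(self.records[0][1])
            for rid, seq in self.records:
                if len(seq) != ref:
                    raise AlignmentError(
                        f"record {rid!r} has length {len(seq)}, expected {ref}"
                    )
                bad = set(seq) - ALPHABET
                if bad:
                    pos = next(i for i, c in enumerate(seq) if c in bad)
                    raise ParseError(
                        f"illegal character {seq[pos]!r} in record {rid!r} "
                        f"at column {pos + 1}"
                    )

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def length(self) -> int:
        return len(self.records[0][1]) if self.records else 0

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    def sequence(self, accession: str) -> str:
        for rid, seq in self.records:
            if rid == accession:
                return seq
        raise KeyError(accession)

    def to_array(self) -> np.ndarray:
        """(n, length) array of single-byte strings; empty (0, 0) if no records."""
        if not self.records:
            return np.empty((0, 0), dtype="U1")
        return np.array([list(seq) for _, seq in self.records], dtype="U1")

    def subset(self, accessions: Iterable[str]) -> "AlignmentSet":
        wanted = set(accessions)
        return AlignmentSet(tuple(r for r in self.records if r[0] in wanted))


@dataclass(frozen=True)
class PopulationMap:
    """Accession -> (population, group) assignment.

    Every population must belong to exactly one group.
    """

    assignments: tuple[tuple[str, str, str], ...]  # (accession, population, group)

    def __post_init__(self) -> None:
        pop_group: dict[str, str] = {}
        seen: set[str] = set()
        for acc, pop, grp in self.assignments:
            if acc in seen:
                raise MappingError(f"accession {acc!r} mapped twice")
            seen.add(acc)
            if pop in pop_group and pop_group[pop] != grp:
                raise MappingError(
                    f"population {pop!r} assigned to groups "
                    f"{pop_group[pop]!r} and {grp!r}"
                )
            pop_group[pop] = grp

    @property
    def accessions(self) -> list[str]:
        return [a for a, _, _ in self.assignments]

    @property
    def populations(self) -> list[str]:
        """Populations in order of first appearance."""
        out: list[str] = []
        for _, pop, _ in self.assignments:
            if pop not in out:
                out.append(pop)
        return out

    @property
    def groups(self) -> list[str]:
        out: list[str] = []
        for _, _, grp in self.assignments:
            if grp not in out:
                out.append(grp)
        return out

    def population_of(self, accession: str) -> str:
        for acc, pop, _ in self.assignments:
            if acc == accession:
                return pop
        raise MappingError(f"accession {accession!r} not in population map")

    def group_of(self, population: str) -> str:
        for _, pop, grp in self.assignments:
            if pop == population:
                return grp
        raise MappingError(f"population {population!r} not in population map")

    def grouping(self) -> dict[str, str]:
        """population -> group."""
        return {pop: self.group_of(pop) for pop in self.populations}

    def members(self, population: str) -> list[str]:
        return [a for a, p, _ in self.assignments if p == population]


@dataclass(frozen=True)
class HaplotypeTable:
    """Unique haplotype sequences with per-population accession counts.

    ``counts`` is a haplotype x population DataFrame of non-negative ints.
    ``sequences`` may be ``None`` for count-only tables (e.g. published
    frequency tables without deposited sequences).
    """

    counts: pd.DataFrame
    sequences: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise InvalidArgument("negative haplotype count")
        if self.sequences is not None:
            missing = set(self.counts.index) - set(self.sequences)
            if missing:
                raise InvalidArgument(f"haplotypes without sequence: {sorted(missing)}")
            seqs = list(self.sequences.values())
            if len(set(seqs)) != len(seqs):
                raise InvalidArgument("haplotype sequences not pairwise distinct")

    @property
    def haplotype_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def populations(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def h(self) -> int:
        return len(self.counts.index)

    @property
    def n(self) -> int:
        return int(self.counts.values.sum())

    def population_counts(self, population: str) -> np.ndarray:
        """Non-zero haplotype counts within one population."""
        col = self.counts[population].to_numpy()
        return col[col > 0]

    def pooled_counts(self) -> np.ndarray:
        tot = self.counts.sum(axis=1).to_numpy()
        return tot[tot > 0]

    def frequencies(self, population: str | None = None) -> np.ndarray:
        c = (
            self.counts.sum(axis=1).to_numpy()
            if population is None
            else self.counts[population].to_numpy()
        )
        tot = c.sum()
        if tot == 0:
            raise InvalidArgument("empty scope for frequencies")
        return c / tot

    def subset(self, population: str) -> "HaplotypeTable":
        """Single-population table keeping only haplotypes present there."""
        col = self.counts[[population]]
        col = col[col[population] > 0]
        seqs = (
            None
            if self.sequences is None
            else {h: self.sequences[h] for h in col.index}
        )
        return HaplotypeTable(col, seqs)

    def expand(self, population: str | None = None) -> list[str]:
        """Haplotype-id label per accession (order: haplotype-major)."""
        cols = self.populations if population is None else [population]
        labels: list[str] = []
        for pop in cols:
            for hap in self.haplotype_ids:
                labels.extend([hap] * int(self.counts.at[hap, pop]))
        return labels

    def relabel(self, name_map: Mapping[str, str]) -> "HaplotypeTable":
        """Rename haplotypes, e.g. to match published Hap numbering."""
        counts = self.counts.rename(index=dict(name_map))
        seqs = (
            None
            if self.sequences is None
            else {name_map.get(h, h): s for h, s in self.sequences.items()}
        )
        return HaplotypeTable(counts, seqs)


@dataclass(frozen=True)
class PolymorphicSite:
    """One independent unit of variation.

    ``start``/``end`` are 0-based half-open alignment columns; a substitution
    site spans one column, an indel event spans its full tandem-gap run.
    ``states`` maps observed state (for indel events: ``'-'`` and ``'+'`` for
    gap carriers / non-carriers) to accession counts.
    """

    start: int
    end: int
    kind: str  # "substitution" | "indel-event"
    states: tuple[tuple[str, int], ...]
    rare: bool | None = None

    @property
    def minor_count(self) -> int:
        """Accessions carrying anything other than the most frequent state."""
        counts = sorted((c for _, c in self.states), reverse=True)
        return sum(counts[1:])


@dataclass(frozen=True)
class PolymorphismTable:
    sites: tuple[PolymorphicSite, ...]
    n: int  # accessions in the alignment the sites were called from

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_rare(self) -> int:
        return sum(1 for s in self.sites if s.rare)

    def to_frame(self) -> pd.DataFrame:
        """1-based inclusive report table."""
        rows = []
        for s in self.sites:
            rows.append(
                {
                    "start": s.start + 1,
                    "end": s.end,
                    "kind": s.kind,
                    "states": ",".join(f"{st}:{c}" for st, c in s.states),
                    "rare": bool(s.rare) if s.rare is not None else "",
                }
            )
        return pd.DataFrame(
            rows, columns=["start", "end", "kind", "states", "rare"]
        )


# ---------------------------------------------------------------------------
# FASTA / TSV I/O
# ---------------------------------------------------------------------------


def read_alignment(path: str | Path) -> AlignmentSet:
    """Read an aligned multi-FASTA; sequences are upper-cased and validated."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ParseError(f"no FASTA records in {path}")
    return AlignmentSet(tuple(records))


def write_alignment(aln: AlignmentSet, path: str | Path) -> None:
    recs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in aln.records]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")  # Biopython wraps at 60 columns


def read_population_map(path: str | Path) -> PopulationMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["accession", "population", "group"]
    if list(df.columns[:3]) != required:
        raise ParseError(
            f"population map must have columns {required}, got {list(df.columns)}"
        )
    return PopulationMap(tuple(df[required].itertuples(index=False, name=None)))


def write_population_map(pmap: PopulationMap, path: str | Path) -> None:
    pd.DataFrame(
        list(pmap.assignments), columns=["accession", "population", "group"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# haplotype collapsing and consensus
# ---------------------------------------------------------------------------


def collapse_haplotypes(
    aln: AlignmentSet,
    pmap: PopulationMap,
    name_map: Mapping[str, str] | None = None,
) -> HaplotypeTable:
    """Collapse accessions to haplotypes under the fifth-state rule.

    Two accessions share a haplotype iff their aligned sequences are
    identical, gaps included, N equal only to N.  Haplotypes are numbered
    Hap1, Hap2, ... by first appearance in the alignment; ``name_map`` may
    relabel them afterwards (e.g. to published numbering).
    """
    unmapped = set(aln.ids) - set(pmap.accessions)
    if unmapped:
        raise MappingError(f"accessions missing from population map: {sorted(unmapped)}")

    hap_of_seq: dict[str, str] = {}
    sequences: dict[str, str] = {}
    order: list[str] = []
    populations = pmap.populations
    counts: dict[str, dict[str, int]] = {}
    for acc, seq in aln.records:
        hap = hap_of_seq.get(seq)
        if hap is None:
            hap = f"Hap{len(order) + 1}"
            hap_of_seq[seq] = hap
            sequences[hap] = seq
            order.append(hap)
            counts[hap] = {p: 0 for p in populations}
        counts[hap][pmap.population_of(acc)] += 1

    frame = pd.DataFrame(
        [[counts[h][p] for p in populations] for h in order],
        index=order,
        columns=populations,
        dtype=int,
    )
    table = HaplotypeTable(frame, sequences)
    if name_map:
        table = table.relabel(name_map)
    return table


def consensus_sequence(
    aln: AlignmentSet,
    weights: Sequence[float] | None = None,
) -> str:
    """Column-wise most frequent state (gap eligible, N ignored).

    Ties break by the fixed order A < C < G < T < ``-``.  ``weights`` allows
    a haplotype-level alignment to be weighted by accession counts; the
    default weights every record equally, so calling this on the full
    accession alignment gives the frequency-weighted consensus and calling
    it on one record per haplotype gives the unweighted variant.
    """
    if aln.n == 0:
        raise InvalidArgument("consensus of empty alignment")
    arr = aln.to_array()
    w = np.ones(aln.n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (aln.n,):
        raise InvalidArgument("weights length must match number of records")
    out = []
    for col in range(aln.length):
        best_state, best_score = None, -1.0
        for state in STATE_ORDER:
            score = float(w[arr[:, col] == state].sum())
            if score > best_score:
                best_state, best_score = state, score
        out.append(best_state if best_score > 0 else "N")
    return "".join(out)


# ---------------------------------------------------------------------------
# polymorphic sites
# ---------------------------------------------------------------------------


def _gap_runs(arr: np.ndarray) -> list[tuple[int, int, frozenset[int]]]:
    """Maximal runs of gap columns with identical carrier sets.

    Returns (start, end, carrier row indices), 0-based half-open.
    """
    n, length = arr.shape
    runs: list[tuple[int, int, frozenset[int]]] = []
    cur_set: frozenset[int] | None = None
    cur_start = 0
    for col in range(length):
        carriers = frozenset(np.flatnonzero(arr[:, col] == GAP).tolist())
        key = carriers if carriers else None
        if key != cur_set:
            if cur_set is not None:
                runs.append((cur_start, col, cur_set))
            cur_set, cur_start = key, col
    if cur_set is not None:
        runs.append((cur_start, length, cur_set))
    return runs


def call_polymorphic_sites(aln: AlignmentSet) -> PolymorphismTable:
    """Call independent units of variation from an alignment.

    Substitution sites are single columns with >= 2 distinct non-gap, non-N
    states among the accessions.  Tandem gaps (maximal runs of gap columns
    with identical carrier sets) are single indel-event sites; adjacent gap
    runs with different carrier sets are separate events.  Monomorphic
    columns are excluded.
    """
    if aln.n == 0:
        raise InvalidArgument("cannot call sites on empty alignment")
    arr = aln.to_array()
    n = aln.n
    sites: list[PolymorphicSite] = []

    for start, end, carriers in _gap_runs(arr):
        if 0 < len(carriers) < n:
            sites.append(
                PolymorphicSite(
                    start,
                    end,
                    "indel-event",
                    (("-", len(carriers)), ("+", n - len(carriers))),
                )
            )

    for col in range(aln.length):
        column = arr[:, col]
        states, counts = np.unique(column[(column != GAP) & (column != "N")], return_counts=True)
        if len(states) >= 2:
            order = np.argsort(-counts, kind="stable")
            sites.append(
                PolymorphicSite(
                    col,
                    col + 1,
                    "substitution",
                    tuple((str(states[i]), int(counts[i])) for i in order),
                )
            )

    sites.sort(key=lambda s: (s.start, s.end))
    return PolymorphismTable(tuple(sites), n)


def classify_rare_sites(poly: PolymorphismTable, n: int | None = None) -> PolymorphismTable:
    """Flag rare sites: minor-state carriers in {1, 2} and below 2% of n."""
    n = poly.n if n is None else n
    if n < 1:
        raise InvalidArgument("n must be >= 1")
    flagged = tuple(
        replace(s, rare=(s.minor_count in (1, 2) and s.minor_count < 0.02 * n))
        for s in poly.sites
    )
    return PolymorphismTable(flagged, poly.n)


# ---------------------------------------------------------------------------
# pairwise event counting and consensus differences
# ---------------------------------------------------------------------------


def count_difference_events(a: str, b: str) -> int:
    """Fifth-state difference count between two aligned sequences, with
    tandem gaps merged: a maximal run of columns where exactly one of the
    pair is gapped counts once; substitutions (both non-gap, unequal,
    neither N) count once per column.  Columns where either is N, or both
    are gaps, are ignored.
    """
    if len(a) != len(b):
        raise InvalidArgument("sequences differ in length")
    events = 0
    in_gap_run = False
    for ca, cb in zip(a, b):
        if ca == "N" or cb == "N":
            in_gap_run = False
            continue
        one_gap = (ca == GAP) != (cb == GAP)
        if one_gap:
            if not in_gap_run:
                events += 1
            in_gap_run = True
        else:
            in_gap_run = False
            if ca != cb and ca != GAP:
                events += 1
    return events


def diff_from_consensus(
    hap_table: HaplotypeTable, consensus: str
) -> dict[str, int]:
    """Per-haplotype count of variation units differing from the consensus."""
    if hap_table.sequences is None:
        raise InvalidArgument("haplotype table carries no sequences")
    any_len = len(next(iter(hap_table.sequences.values())))
    if len(consensus) != any_len:
        raise InvalidArgument(
            f"consensus length {len(consensus)} != alignment length {any_len}"
        )
    return {
        hap: count_difference_events(seq, consensus)
        for hap, seq in hap_table.sequences.items()
    }
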