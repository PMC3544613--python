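"""IUPAC motif scanning, conservation classification, and permutation
enrichment for promoter haplotypes.

Scanning is exhaustive: every position of the ungapped haplotype sequence
where the IUPAC consensus matches yields one hit, overlapping matches
included.  Hits carry both ungapped sequence coordinates and alignment
coordinates, so occurrences can be compared across haplotypes at the
homologous location.  A *locus* is a set of hits of the same motif whose
alignment intervals overlap; a locus is *conserved* when every haplotype
has a hit there.

Enrichment follows the sequence-reshuffling recipe: the observed count of
a motif (or pooled category) on a sequence is compared with counts on
composition-preserving reshuffles of the same sequence, with empirical
p = (1 + #{null >= observed}) / (1 + reps).  Mononucleotide permutation is
the default; a dinucleotide-preserving Euler-path shuffle
(Altschul-Erickson) is available because motif nulls are sensitive to
dinucleotide content.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import GAP, HaplotypeTable
from .errors import InvalidArgument, ParseError, UnknownMotif

IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Motif:
    motif_id: str
    iupac: str
    tf_name: str
    category: str

    def __post_init__(self) -> None:
        bad = set(self.iupac.upper()) - set(IUPAC_CODES)
        if bad:
            raise ParseError(
                f"motif {self.motif_id!r}: illegal IUPAC symbol(s) {sorted(bad)}"
            )
        if len(self.iupac) < 4:
            raise ParseError(
                f"motif {self.motif_id!r}: pattern shorter than 4 bases"
            )


@dataclass(frozen=True)
class MotifLibrary:
    motifs: tuple[Motif, ...]

    def __post_init__(self) -> None:
        ids = [m.motif_id for m in self.motifs]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ParseError(f"duplicate motif id {dup!r}")

    def __len__(self) -> int:
        return len(self.motifs)

    def __iter__(self):
        return iter(self.motifs)

    def get(self, motif_id: str) -> Motif:
        for m in self.motifs:
            if m.motif_id == motif_id:
                return m
        raise UnknownMotif(f"motif {motif_id!r} not in library")

    @property
    def categories(self) -> list[str]:
        out: list[str] = []
        for m in self.motifs:
            if m.category not in out:
                out.append(m.category)
        return out


def load_motif_library(path: str | Path) -> MotifLibrary:
    """Read a 4-column TSV: motif_id, iupac, tf_name, category."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return MotifLibrary(())
    required = ["motif_id", "iupac", "tf_name", "category"]
    if list(df.columns[:4]) != required:
        raise ParseError(f"motif library must have columns {required}")
    motifs = []
    for row_num, row in enumerate(df.itertuples(index=False), start=2):
        try:
            motifs.append(Motif(row.motif_id, row.iupac.upper(), row.tf_name, row.category))
        except ParseError as exc:
            raise ParseError(f"row {row_num}: {exc}") from exc
    return MotifLibrary(tuple(motifs))


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------


@lru_cache(maxsize=1024)
def iupac_regex(iupac: str) -> re.Pattern:
    """Overlap-tolerant compiled pattern for an IUPAC consensus."""
    parts = []
    for sym in iupac.upper():
        states = sorted(IUPAC_CODES[sym])
        parts.append(states[0] if len(states) == 1 else "[" + "".join(states) + "]")
    return re.compile("(?=(" + "".join(parts) + "))")


def count_matches(sequence: str, iupac: str) -> int:
    """Number of (overlapping) matches of the consensus on one strand."""
    return sum(1 for _ in iupac_regex(iupac).finditer(sequence))


@dataclass(frozen=True)
class MotifHit:
    haplotype_id: str
    motif_id: str
    aln_start: int  # 0-based half-open alignment columns
    aln_end: int
    seq_start: int  # 0-based half-open ungapped coordinates
    seq_end: int
    strand: str  # "+" | "-"


def _degap(seq: str) -> tuple[str, list[int]]:
    """(ungapped sequence, alignment column of each ungapped position)."""
    chars, cols = [], []
    for col, c in enumerate(seq):
        if c != GAP:
            chars.append(c)
            cols.append(col)
    return "".join(chars), cols


def scan_motifs(
    hap_table: HaplotypeTable,
    lib: MotifLibrary,
    strands: str = "forward",
) -> list[MotifHit]:
    """Scan every haplotype against every motif.

    Returns hits in deterministic order (haplotype, position, motif).
    With ``strands="both"`` the reverse strand is scanned by matching the
    reverse-complemented pattern on the forward sequence, so coordinates
    always refer to the forward strand.
    """
    if strands not in ("forward", "both"):
        raise InvalidArgument(f"unknown strand mode {strands!r}")
    if hap_table.sequences is None:
        raise InvalidArgument("haplotype table carries no sequences")
    hits: list[MotifHit] = []
    for hap in hap_table.haplotype_ids:
        ungapped, cols = _degap(hap_table.sequences[hap])
        if not ungapped:
            raise InvalidArgument(f"haplotype {hap!r} empty after degapping")
        per_hap: list[MotifHit] = []
        for motif in lib:
            patterns = [(motif.iupac, "+")]
            if strands == "both":
                patterns.append((reverse_complement(motif.iupac), "-"))
            for pattern, strand in patterns:
                m = len(pattern)
                for match in iupac_regex(pattern).finditer(ungapped):
                    s = match.start()
                    per_hap.append(
                        MotifHit(
                            hap,
                            motif.motif_id,
                            cols[s],
                            cols[s + m - 1] + 1,
                            s,
                            s + m,
                            strand,
                        )
                    )
        per_hap.sort(key=lambda h: (h.seq_start, h.motif_id, h.strand))
        hits.extend(per_hap)
    return hits


def hits_to_frame(hits: list[MotifHit]) -> pd.DataFrame:
    """1-based inclusive report table."""
    return pd.DataFrame(
        [
            {
                "haplotype": h.haplotype_id,
                "motif": h.motif_id,
                "aln_start": h.aln_start + 1,
                "aln_end": h.aln_end,
                "seq_start": h.seq_start + 1,
                "seq_end": h.seq_end,
                "strand": h.strand,
            }
            for h in hits
        ],
        columns=[
            "haplotype",
            "motif",
            "aln_start",
            "aln_end",
            "seq_start",
            "seq_end",
            "strand",
        ],
    )


# ---------------------------------------------------------------------------
# conservation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MotifLocus:
    motif_id: str
    aln_start: int
    aln_end: int
    present_in: tuple[str, ...]
    conserved: bool


@dataclass(frozen=True)
class ConservationSummary:
    loci: tuple[MotifLocus, ...]
    h: int

    @property
    def n_conserved(self) -> int:
        return sum(1 for l in self.loci if l.conserved)

    @property
    def n_non_conserved(self) -> int:
        return len(self.loci) - self.n_conserved

    @property
    def conserved_fraction(self) -> float:
        if not self.loci:
            raise InvalidArgument("no loci")
        return self.n_conserved / len(self.loci)

    def category_proportions(self, lib: MotifLibrary) -> pd.DataFrame:
        """Per conservation class, proportion of loci in each category."""
        rows = []
        for cls in ("conserved", "non-conserved"):
            loci = [l for l in self.loci if l.conserved == (cls == "conserved")]
            counts: dict[str, int] = {}
            for l in loci:
                cat = lib.get(l.motif_id).category
                counts[cat] = counts.get(cat, 0) + 1
            total = sum(counts.values())
            for cat, c in sorted(counts.items()):
                rows.append(
                    {"class": cls, "category": cat, "count": c, "proportion": c / total}
                )
        return pd.DataFrame(rows, columns=["class", "category", "count", "proportion"])


def classify_conservation(
    hits: list[MotifHit], h: int, haplotype_ids: list[str] | None = None
) -> ConservationSummary:
    """Cluster hits of one motif by overlapping alignment intervals into
    loci; a locus is conserved iff present in all ``h`` haplotypes.
    Classification is invariant to haplotype and hit order.
    """
    if h <= 0:
        raise InvalidArgument("h must be positive")
    by_motif: dict[str, list[MotifHit]] = {}
    for hit in hits:
        by_motif.setdefault(hit.motif_id, []).append(hit)
    loci: list[MotifLocus] = []
    for motif_id in sorted(by_motif):
        group = sorted(by_motif[motif_id], key=lambda x: (x.aln_start, x.aln_end))
        cluster: list[MotifHit] = []
        end = -1
        for hit in group:
            if cluster and hit.aln_start >= end:
                loci.append(_make_locus(motif_id, cluster, h))
                cluster, end = [], -1
            cluster.append(hit)
            end = max(end, hit.aln_end)
        if cluster:
            loci.append(_make_locus(motif_id, cluster, h))
    loci.sort(key=lambda l: (l.aln_start, l.aln_end, l.motif_id))
    return ConservationSummary(tuple(loci), h)


def _make_locus(motif_id: str, cluster: list[MotifHit], h: int) -> MotifLocus:
    present = tuple(sorted({x.haplotype_id for x in cluster}))
    return MotifLocus(
        motif_id,
        min(x.aln_start for x in cluster),
        max(x.aln_end for x in cluster),
        present,
        len(present) == h,
    )


# ---------------------------------------------------------------------------
# category aggregation
# ---------------------------------------------------------------------------


def aggregate_categories(
    hits: list[MotifHit],
    lib: MotifLibrary,
    scope_of: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Hit counts per category per scope (default scope = haplotype).

    ``scope_of`` maps haplotype id to a coarser scope (e.g. population);
    the returned frame has one row per scope with category columns and a
    ``total`` column.
    """
    cat_of = {m.motif_id: m.category for m in lib}
    for hit in hits:
        if hit.motif_id not in cat_of:
            raise UnknownMotif(f"hit references unknown motif {hit.motif_id!r}")
    categories = lib.categories
    counts: dict[str, dict[str, int]] = {}
    for hit in hits:
        scope = scope_of.get(hit.haplotype_id, hit.haplotype_id) if scope_of else hit.haplotype_id
        row = counts.setdefault(scope, {c: 0 for c in categories})
        row[cat_of[hit.motif_id]] += 1
    frame = pd.DataFrame(
        [[counts[s][c] for c in categories] for s in sorted(counts)],
        index=sorted(counts),
        columns=categories,
        dtype=int,
    )
    frame["total"] = frame.sum(axis=1)
    return frame


# ---------------------------------------------------------------------------
# permutation enrichment
# ---------------------------------------------------------------------------


def mononucleotide_shuffle(sequence: str, rng: np.random.Generator) -> str:
    arr = np.array(list(sequence), dtype="U1")
    return "".join(rng.permutation(arr))


def dinucleotide_shuffle(sequence: str, rng: np.random.Generator) -> str:
    """Altschul-Erickson shuffle preserving exact dinucleotide counts.

    Builds the multigraph of consecutive base pairs, draws a uniform
    last-edge arborescence towards the terminal base by rejection, then
    walks a random Euler path.
    """
    if len(sequence) < 3:
        return sequence
    s = sequence
    vertices = sorted(set(s))
    edges: dict[str, list[str]] = {v: [] for v in vertices}
    for a, b in zip(s, s[1:]):
        edges[a].append(b)
    last = s[-1]

    non_terminal = [v for v in vertices if v != last and edges[v]]
    for _ in range(10000):
        last_edge = {v: edges[v][int(rng.integers(len(edges[v])))] for v in non_terminal}
        # every non-terminal vertex must reach `last` through last-edges
        ok = True
        for v in non_terminal:
            seen = set()
            cur = v
            while cur != last:
                if cur in seen or cur not in last_edge:
                    ok = False
                    break
                seen.add(cur)
                cur = last_edge[cur]
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - rejection virtually always succeeds
        raise RuntimeError("dinucleotide shuffle failed to find an arborescence")

    shuffled: dict[str, list[str]] = {}
    for v in vertices:
        rest = list(edges[v])
        if v in last_edge:
            rest.remove(last_edge[v])
        rng.shuffle(rest)
        shuffled[v] = rest + ([last_edge[v]] if v in last_edge else [])

    out = [s[0]]
    cur = s[0]
    pos = {v: 0 for v in vertices}
    for _ in range(len(s) - 1):
        nxt = shuffled[cur][pos[cur]]
        pos[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


SHUFFLE_MODES = {
    "mono": mononucleotide_shuffle,
    "dinucleotide": dinucleotide_shuffle,
}


@dataclass(frozen=True)
class EnrichmentResult:
    target: str  # motif_id or category name
    observed: int
    null_mean: float
    null_sd: float
    p: float
    reps: int
    seed: int
    shuffle_mode: str


def permutation_enrichment(
    sequence: str,
    target: str,
    lib: MotifLibrary,
    reps: int = 10000,
    shuffle_mode: str = "mono",
    seed: int = 0,
    by_category: bool = False,
) -> EnrichmentResult:
    """Permutation test for over-representation of one motif (or pooled
    category) on an ungapped sequence.

    p = (1 + #{null >= observed}) / (1 + reps).
    """
    if reps < 100:
        raise InvalidArgument("reps must be >= 100")
    if shuffle_mode not in SHUFFLE_MODES:
        raise InvalidArgument(f"unknown shuffle mode {shuffle_mode!r}")
    sequence = sequence.upper().replace(GAP, "")
    if by_category:
        patterns = [m.iupac for m in lib if m.category == target]
        if not patterns:
            raise UnknownMotif(f"no motifs in category {target!r}")
    else:
        patterns = [lib.get(target).iupac]
    if min(len(p) for p in patterns) >= len(sequence):
        raise InvalidArgument("sequence not longer than the motif")

    def score(seq: str) -> int:
        return sum(count_matches(seq, p) for p in patterns)

    observed = score(sequence)
    rng = np.random.default_rng(seed)
    shuffle = SHUFFLE_MODES[shuffle_mode]
    null = np.empty(reps, dtype=int)
    for i in range(reps):
        null[i] = score(shuffle(sequence, rng))
    hits = int(np.sum(null >= observed))
    return EnrichmentResult(
        target=target,
        observed=observed,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=0)),
        p=(hits + 1) / (reps + 1),
        reps=reps,
        seed=seed,
        shuffle_mode=shuffle_mode,
    )
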