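"""Diversity and neutrality statistics: h, Hd, pi, k, S, eta, eta_s,
Tajima's D and Fu & Li's F*, with a coalescent permutation null.

Gap handling for the sequence statistics comes in two modes:

``complete``
    Complete deletion: every column containing a gap or an N in any
    included sequence is removed before counting; the effective length is
    the number of remaining columns.  This is the conventional behaviour of
    diversity software and the default here.

``fifth-state``
    Gaps are a fifth character state and each tandem-gap run (identical
    carrier set) is one unit of variation; effective length is the full
    alignment length.

Tajima's D follows the 1989 formulation:

    D = (k - S/a1) / sqrt(e1*S + e2*S*(S-1))

with a1 = sum_{i<n} 1/i, a2 = sum_{i<n} 1/i^2, b1 = (n+1)/(3(n-1)),
b2 = 2(n^2+n+3)/(9n(n-1)), c1 = b1 - 1/a1,
c2 = b2 - (n+2)/(a1 n) + a2/a1^2, e1 = c1/a1, e2 = c2/(a1^2+a2).

Fu & Li's F* (no outgroup) uses the total number of mutations eta and the
number of singleton mutations eta_s:

    F* = (k - eta_s*(n-1)/n) / sqrt(u_F*eta + v_F*eta^2)

with the corrected variance coefficients

    v_F = [ (2n^3 + 110n^2 - 255n + 153) / (9 n^2 (n-1))
            + 2 (n-1) a_n / n^2 - 8 b_n / n ] / (a_n^2 + b_n)
    u_F = [ (4n^2 + 19n + 3 - 12 (n+1) a_{n+1}) / (3 n (n-1)) ] / a_n - v_F

where a_n = sum_{i<n} 1/i and b_n = sum_{i<n} 1/i^2.

Significance is assessed against a neutral Kingman-coalescent null
conditioned on the observed number of segregating sites: a random
genealogy is drawn, S mutations are dropped on branches with probability
proportional to branch length, and the statistic is recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import GAP, AlignmentSet, HaplotypeTable, call_polymorphic_sites
from .errors import InvalidArgument, UndefinedStatistic

GAP_MODES = ("complete", "fifth-state")


# ---------------------------------------------------------------------------
# haplotype diversity
# ---------------------------------------------------------------------------


def haplotype_diversity(counts, n: int | None = None) -> float:
    """Nei's unbiased haplotype diversity, Hd = n (1 - sum p_i^2) / (n - 1).

    ``counts`` are per-haplotype accession counts; zero entries are allowed.
    """
    c = np.asarray(list(counts), dtype=float)
    if (c < 0).any():
        raise InvalidArgument("negative haplotype count")
    total = c.sum()
    if n is None:
        n = int(round(total))
    elif n != total:
        raise InvalidArgument(f"counts sum to {total:g}, not n={n}")
    if n < 2:
        raise UndefinedStatistic("Hd requires n >= 2")
    p = c / n
    return float(n * (1.0 - np.sum(p**2)) / (n - 1))


# ---------------------------------------------------------------------------
# sequence summaries (weighted by haplotype counts)
# ---------------------------------------------------------------------------


def _as_haplotypes(
    data: AlignmentSet | HaplotypeTable,
) -> tuple[list[str], np.ndarray]:
    """Reduce input to unique sequences plus accession weights."""
    if isinstance(data, AlignmentSet):
        seqs: list[str] = []
        weights: list[int] = []
        index: dict[str, int] = {}
        for _, seq in data.records:
            if seq in index:
                weights[index[seq]] += 1
            else:
                index[seq] = len(seqs)
                seqs.append(seq)
                weights.append(1)
        return seqs, np.array(weights, dtype=float)
    if isinstance(data, HaplotypeTable):
        if data.sequences is None:
            raise InvalidArgument("haplotype table carries no sequences")
        seqs = [data.sequences[h] for h in data.haplotype_ids]
        weights = data.counts.sum(axis=1).to_numpy(dtype=float)
        keep = weights > 0
        return [s for s, k in zip(seqs, keep) if k], weights[keep]
    raise InvalidArgument(f"unsupported input type {type(data).__name__}")


def _complete_columns(seqs: list[str]) -> np.ndarray:
    arr = np.array([list(s) for s in seqs], dtype="U1")
    ok = ~np.any((arr == GAP) | (arr == "N"), axis=0)
    return arr[:, ok]


def _pair_differences(seqs: list[str], gap_mode: str) -> tuple[np.ndarray, int]:
    """(h, h) matrix of per-pair difference counts and the effective length."""
    from .alignment import count_difference_events

    if gap_mode not in GAP_MODES:
        raise InvalidArgument(f"unknown gap mode {gap_mode!r}")
    h = len(seqs)
    d = np.zeros((h, h))
    if gap_mode == "complete":
        arr = _complete_columns(seqs)
        eff_len = arr.shape[1]
        for i in range(h):
            for j in range(i + 1, h):
                d[i, j] = d[j, i] = int(np.sum(arr[i] != arr[j]))
    else:
        eff_len = len(seqs[0]) if seqs else 0
        for i in range(h):
            for j in range(i + 1, h):
                d[i, j] = d[j, i] = count_difference_events(seqs[i], seqs[j])
    return d, eff_len


def nucleotide_diversity(
    data: AlignmentSet | HaplotypeTable, gap_mode: str = "complete"
) -> tuple[float, float]:
    """(pi, k): per-site nucleotide diversity and mean pairwise differences.

    k averages the difference count over all n(n-1)/2 accession pairs
    (haplotype multiplicities respected); pi = k / effective length.
    """
    seqs, w = _as_haplotypes(data)
    n = w.sum()
    if n < 2:
        raise UndefinedStatistic("pi requires n >= 2")
    d, eff_len = _pair_differences(seqs, gap_mode)
    total = float(w @ d @ w) / 2.0  # within-haplotype pairs contribute 0
    k = total / (n * (n - 1) / 2.0)
    if eff_len == 0:
        raise UndefinedStatistic("zero effective length after complete deletion")
    return k / eff_len, k


def mutation_counts(
    data: AlignmentSet | HaplotypeTable, gap_mode: str = "complete"
) -> tuple[int, int, int]:
    """(S, eta, eta_s) for the sample.

    S: segregating sites (indel events count once in fifth-state mode).
    eta: total mutations; a site with m observed states contributes m - 1.
    eta_s: singleton mutations, i.e. states carried by exactly one sequence
    (at biallelic sites the state carried by n - 1 sequences is not itself a
    mutation, so only the count-1 minor state is a singleton).
    """
    seqs, w = _as_haplotypes(data)
    n = int(round(w.sum()))
    if gap_mode not in GAP_MODES:
        raise InvalidArgument(f"unknown gap mode {gap_mode!r}")

    S = eta = eta_s = 0
    if gap_mode == "complete":
        arr = _complete_columns(seqs)
        for col in range(arr.shape[1]):
            states: dict[str, float] = {}
            for s, wt in zip(arr[:, col], w):
                states[str(s)] = states.get(str(s), 0.0) + wt
            if len(states) >= 2:
                S += 1
                eta += len(states) - 1
                counts = sorted(states.values(), reverse=True)
                # non-majority states carried by exactly one sequence
                eta_s += sum(1 for c in counts[1:] if round(c) == 1)
    else:
        aln = _expand_weighted(seqs, w)
        table = call_polymorphic_sites(aln)
        for site in table.sites:
            S += 1
            eta += len(site.states) - 1
            counts = sorted((c for _, c in site.states), reverse=True)
            eta_s += sum(1 for c in counts[1:] if c == 1)
    return S, eta, eta_s


def _expand_weighted(seqs: list[str], w: np.ndarray) -> AlignmentSet:
    records = []
    for i, (seq, wt) in enumerate(zip(seqs, w)):
        for j in range(int(round(wt))):
            records.append((f"h{i}_{j}", seq))
    return AlignmentSet(tuple(records))


# ---------------------------------------------------------------------------
# neutrality statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TajimaCoefficients:
    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_coefficients(n: int) -> TajimaCoefficients:
    if n < 4:
        raise UndefinedStatistic("Tajima's D requires n >= 4")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaCoefficients(n, a1, a2, b1, b2, c1, c2, e1, e2)


def tajimas_d(S: int, k: float, n: int) -> float | None:
    """Tajima's D from segregating sites and mean pairwise differences.

    Returns None (missing) when S == 0.
    """
    coef = tajima_coefficients(n)
    if S < 0:
        raise InvalidArgument("S must be >= 0")
    if S == 0:
        return None
    var = coef.e1 * S + coef.e2 * S * (S - 1)
    return float((k - S / coef.a1) / np.sqrt(var))


@dataclass(frozen=True)
class FuLiCoefficients:
    n: int
    a_n: float
    b_n: float
    u_F: float
    v_F: float


def fu_li_coefficients(n: int) -> FuLiCoefficients:
    if n < 4:
        raise UndefinedStatistic("Fu & Li's F* requires n >= 4")
    i = np.arange(1, n)
    a_n = float(np.sum(1.0 / i))
    b_n = float(np.sum(1.0 / i**2))
    a_n1 = a_n + 1.0 / n  # a_{n+1}
    v_F = (
        (2.0 * n**3 + 110.0 * n**2 - 255.0 * n + 153.0) / (9.0 * n**2 * (n - 1))
        + 2.0 * (n - 1) * a_n / n**2
        - 8.0 * b_n / n
    ) / (a_n**2 + b_n)
    u_F = (
        (4.0 * n**2 + 19.0 * n + 3.0 - 12.0 * (n + 1) * a_n1) / (3.0 * n * (n - 1))
    ) / a_n - v_F
    return FuLiCoefficients(n, a_n, b_n, u_F, v_F)


def fu_li_f_star(eta: int, eta_s: int, k: float, n: int) -> float | None:
    """Fu & Li's F* (no outgroup); None when eta == 0."""
    coef = fu_li_coefficients(n)
    if not eta >= eta_s >= 0:
        raise InvalidArgument("require eta >= eta_s >= 0")
    if eta == 0:
        return None
    var = coef.u_F * eta + coef.v_F * eta**2
    return float((k - eta_s * (n - 1) / n) / np.sqrt(var))


# ---------------------------------------------------------------------------
# neutral coalescent null conditioned on S
# ---------------------------------------------------------------------------


def simulate_neutral_summaries(
    n: int, S: int, rng: np.random.Generator
) -> tuple[float, int, int]:
    """Draw (k, eta, eta_s) from the standard n-coalescent with exactly S
    infinite-sites mutations dropped uniformly on total branch length.

    Singletons are mutations whose derived or ancestral state is private to
    one sequence (carrier count 1 or n - 1), matching outgroup-free counting.
    """
    if n < 2 or S < 0:
        raise InvalidArgument("need n >= 2 and S >= 0")
    sizes = np.ones(n, dtype=int)
    seg_sizes: list[int] = []
    seg_lengths: list[float] = []
    active = list(range(n))
    subtended = {i: 1 for i in active}
    while len(active) > 1:
        i = len(active)
        t = rng.exponential(2.0 / (i * (i - 1)))
        for lin in active:
            seg_sizes.append(subtended[lin])
            seg_lengths.append(t)
        a, b = rng.choice(len(active), size=2, replace=False)
        la, lb = active[a], active[b]
        new = max(subtended.keys()) + 1
        subtended[new] = subtended[la] + subtended[lb]
        active = [l for l in active if l not in (la, lb)] + [new]
    lengths = np.array(seg_lengths)
    sizes_arr = np.array(seg_sizes)
    if S == 0:
        return 0.0, 0, 0
    probs = lengths / lengths.sum()
    picks = rng.choice(len(lengths), size=S, p=probs)
    carriers = sizes_arr[picks]
    k = float(np.sum(2.0 * carriers * (n - carriers)) / (n * (n - 1)))
    eta = S
    eta_s = int(np.sum((carriers == 1) | (carriers == n - 1)))
    return k, eta, eta_s


def neutrality_pvalue(
    statistic: str,
    observed: float,
    n: int,
    S: int,
    reps: int = 1000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Two-tailed empirical p for Tajima's D or Fu & Li's F* against the
    neutral coalescent conditioned on S, with a +1 pseudo-count.
    """
    if statistic not in ("D", "F*"):
        raise InvalidArgument(f"unknown statistic {statistic!r}")
    if reps < 100:
        raise InvalidArgument("reps must be >= 100")
    if S < 1:
        raise UndefinedStatistic("p-value undefined for S = 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hits = 0
    for _ in range(reps):
        k, eta, eta_s = simulate_neutral_summaries(n, S, rng)
        if statistic == "D":
            sim = tajimas_d(S, k, n)
        else:
            sim = fu_li_f_star(eta, eta_s, k, n)
        if sim is not None and abs(sim) >= abs(observed) - 1e-12:
            hits += 1
    return (hits + 1) / (reps + 1)


# ---------------------------------------------------------------------------
# per-scope summary
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiversityStats:
    scope: str
    n: int
    h: int
    Hd: float
    pi: float
    k: float
    S: int
    eta: int
    eta_s: int
    tajima_d: float | None
    fu_li_f_star: float | None
    p_tajima: float | None = None
    p_fu_li: float | None = None


def diversity_summary(
    hap_table: HaplotypeTable,
    scope: str | None = None,
    gap_mode: str = "complete",
    pvalue_reps: int = 0,
    seed: int = 0,
) -> DiversityStats:
    """Full Table-4-style summary for one population (or pooled if None)."""
    table = hap_table if scope is None else hap_table.subset(scope)
    counts = table.pooled_counts()
    n = int(counts.sum())
    hd = haplotype_diversity(counts)
    pi, k = nucleotide_diversity(table, gap_mode)
    S, eta, eta_s = mutation_counts(table, gap_mode)
    d = tajimas_d(S, k, n) if n >= 4 else None
    f = fu_li_f_star(eta, eta_s, k, n) if n >= 4 else None
    p_d = p_f = None
    if pvalue_reps and S >= 1 and d is not None:
        p_d = neutrality_pvalue("D", d, n, S, pvalue_reps, seed)
        p_f = neutrality_pvalue("F*", f, n, S, pvalue_reps, seed + 1)
    return DiversityStats(
        scope or "total", n, len(counts), hd, pi, k, S, eta, eta_s, d, f, p_d, p_f
    )
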