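"""Hierarchical analysis of molecular variance (AMOVA) with Phi statistics.

Two-level hierarchy: groups / populations within groups / accessions within
populations.  Sums of squares follow the Excoffier convention: for a unit of
M members, SS = (1/M) * sum_{i<j} delta^2_ij, computed block-wise over
haplotypes so the N x N accession matrix is never materialised.  With the
identity distance (delta^2 = 1 between different haplotypes, 0 otherwise)
this is the "haplotype frequency" AMOVA and admits the closed form

    SS_unit = (M^2 - sum_k c_k^2) / (2 M)

for haplotype counts c_k.  Variance components use the standard
unequal-sample-size coefficients:

    Vc = SS_within / (N - P)
    Vb = (MS_pops - Vc) / n'        n'  = (N - sum_g sum_{p in g} n_p^2 / N_g) / (P - G)
    Va = (MS_groups - Vc - n'' Vb) / n'''
        n''  = (sum_g sum_{p in g} n_p^2 / N_g - sum_p n_p^2 / N) / (G - 1)
        n''' = (N - sum_g N_g^2 / N) / (G - 1)

Phi statistics: Phi_CT = Va/V, Phi_SC = Vb/(Vb+Vc), Phi_ST = (Va+Vb)/V.

Negative variance components are reported as computed and flagged, never
truncated.  Rounding happens only at report time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import HaplotypeTable, PopulationMap, count_difference_events
from .errors import InvalidArgument, InvalidHierarchy, UndefinedStatistic

DISTANCE_MODES = ("identity", "differences")


@dataclass(frozen=True)
class DistanceSpec:
    """How squared distances between haplotypes are defined.

    ``identity``: 0 if same haplotype else 1 (frequency-based AMOVA).
    ``differences``: squared count of fifth-state difference events between
    the haplotype sequences.  ``matrix`` may supply a precomputed haplotype
    x haplotype squared-distance matrix instead.
    """

    mode: str = "identity"
    matrix: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode not in DISTANCE_MODES:
            raise InvalidArgument(f"unknown distance mode {self.mode!r}")
        if self.matrix is not None:
            m = np.asarray(self.matrix, dtype=float)
            if m.ndim != 2 or m.shape[0] != m.shape[1]:
                raise InvalidArgument("distance matrix must be square")
            if not np.allclose(m, m.T):
                raise InvalidArgument("distance matrix must be symmetric")
            if np.any(np.diag(m) != 0):
                raise InvalidArgument("distance matrix must have zero diagonal")
            if np.any(m < 0):
                raise InvalidArgument("distance matrix must be non-negative")


@dataclass(frozen=True)
class AmovaResult:
    ss_among_groups: float
    ss_among_pops_within: float
    ss_within: float
    ss_total: float
    df: tuple[int, int, int, int]  # (G-1, P-G, N-P, N-1)
    Va: float
    Vb: float
    Vc: float
    pct: tuple[float, float, float]
    phi_CT: float | None
    phi_SC: float | None
    phi_ST: float | None
    n_prime: float
    n_dprime: float
    n_tprime: float
    negative_components: bool = False
    p_values: dict | None = None

    def to_frame(self) -> pd.DataFrame:
        """Report table shaped like a standard AMOVA table (3 d.p.)."""
        rows = [
            ("Among groups", self.df[0], self.ss_among_groups, self.Va, self.pct[0]),
            (
                "Among populations within groups",
                self.df[1],
                self.ss_among_pops_within,
                self.Vb,
                self.pct[1],
            ),
            ("Within populations", self.df[2], self.ss_within, self.Vc, self.pct[2]),
            ("Total", self.df[3], self.ss_total, self.Va + self.Vb + self.Vc, np.nan),
        ]
        df = pd.DataFrame(
            rows,
            columns=[
                "source",
                "df",
                "sum_of_squares",
                "variance_component",
                "percentage",
            ],
        )
        for col in ("sum_of_squares", "variance_component"):
            df[col] = df[col].round(3)
        df["percentage"] = df["percentage"].round(1)
        return df


# ---------------------------------------------------------------------------
# distances and sums of squares
# ---------------------------------------------------------------------------


def haplotype_distance_matrix(
    hap_table: HaplotypeTable, spec: DistanceSpec | None = None
) -> np.ndarray:
    """Squared-distance matrix between haplotypes (h x h)."""
    spec = spec or DistanceSpec()
    h = hap_table.h
    if spec.matrix is not None:
        m = np.asarray(spec.matrix, dtype=float)
        if m.shape != (h, h):
            raise InvalidArgument(f"matrix shape {m.shape} != ({h}, {h})")
        return m
    if spec.mode == "identity":
        return 1.0 - np.eye(h)
    if hap_table.sequences is None:
        raise InvalidArgument("differences mode needs haplotype sequences")
    seqs = [hap_table.sequences[i] for i in hap_table.haplotype_ids]
    d2 = np.zeros((h, h))
    for i in range(h):
        for j in range(i + 1, h):
            d = count_difference_events(seqs[i], seqs[j])
            d2[i, j] = d2[j, i] = float(d) ** 2
    return d2


def _unit_ss(counts: np.ndarray, d2: np.ndarray) -> float:
    """SS for one unit from per-haplotype counts: (1/M) sum_{i<j} delta^2."""
    m = counts.sum()
    if m == 0:
        return 0.0
    return float(counts @ d2 @ counts) / (2.0 * m)


def amova_sums_of_squares(
    hap_table: HaplotypeTable,
    pmap: PopulationMap,
    spec: DistanceSpec | None = None,
) -> dict:
    """SS decomposition and degrees of freedom for the two-level hierarchy."""
    spec = spec or DistanceSpec()
    pops = [p for p in pmap.populations if p in hap_table.populations]
    if len(pops) < 2:
        raise InvalidHierarchy("AMOVA needs >= 2 populations")
    grouping = pmap.grouping()
    groups: dict[str, list[str]] = {}
    for pop in pops:
        groups.setdefault(grouping[pop], []).append(pop)
    G, P = len(groups), len(pops)
    if G < 1 or (G > 1 and P == G and P > 1 and any(len(v) == 0 for v in groups.values())):
        raise InvalidHierarchy("empty group")

    d2 = haplotype_distance_matrix(hap_table, spec)
    C = hap_table.counts[pops].to_numpy(dtype=float)
    pop_sizes = C.sum(axis=0)
    if np.any(pop_sizes < 1):
        raise InvalidHierarchy("every population needs n >= 1")
    N = int(pop_sizes.sum())

    ss_total = _unit_ss(C.sum(axis=1), d2)
    ss_within = sum(_unit_ss(C[:, j], d2) for j in range(P))
    ss_groups = 0.0
    for members in groups.values():
        idx = [pops.index(p) for p in members]
        ss_groups += _unit_ss(C[:, idx].sum(axis=1), d2)
    ss_among_pops_within = ss_groups - ss_within
    ss_among_groups = ss_total - ss_groups

    return {
        "ss_total": ss_total,
        "ss_within": ss_within,
        "ss_among_pops_within": ss_among_pops_within,
        "ss_among_groups": ss_among_groups,
        "df": (G - 1, P - G, N - P, N - 1),
        "pops": pops,
        "groups": groups,
        "pop_sizes": dict(zip(pops, pop_sizes)),
        "N": N,
    }


def variance_components(
    ss: dict,
) -> tuple[float, float, float, tuple[float, float, float], float, float, float]:
    """(Va, Vb, Vc, pct, n', n'', n''') from the SS decomposition."""
    G = len(ss["groups"])
    P = len(ss["pops"])
    N = ss["N"]
    sizes = ss["pop_sizes"]
    df_a, df_b, df_c, _ = ss["df"]
    if df_c <= 0 or df_b <= 0 or df_a <= 0:
        raise InvalidHierarchy("degrees of freedom must be positive at each level")

    Vc = ss["ss_within"] / df_c
    sum_np2 = sum(v**2 for v in sizes.values())
    group_sizes = {g: sum(sizes[p] for p in members) for g, members in ss["groups"].items()}
    sum_g = sum(
        sum(sizes[p] ** 2 for p in members) / group_sizes[g]
        for g, members in ss["groups"].items()
    )
    n_prime = (N - sum_g) / (P - G)
    n_dprime = (sum_g - sum_np2 / N) / (G - 1)
    n_tprime = (N - sum(v**2 for v in group_sizes.values()) / N) / (G - 1)

    ms_pops = ss["ss_among_pops_within"] / df_b
    ms_groups = ss["ss_among_groups"] / df_a
    Vb = (ms_pops - Vc) / n_prime
    Va = (ms_groups - Vc - n_dprime * Vb) / n_tprime

    total = Va + Vb + Vc
    if total == 0:
        raise UndefinedStatistic("zero total variance: percentages undefined")
    pct = tuple(100.0 * v / total for v in (Va, Vb, Vc))
    return Va, Vb, Vc, pct, n_prime, n_dprime, n_tprime


def phi_statistics(
    Va: float, Vb: float, Vc: float
) -> tuple[float | None, float | None, float | None]:
    """(Phi_CT, Phi_SC, Phi_ST); None where the denominator is zero."""
    V = Va + Vb + Vc
    if V == 0:
        raise UndefinedStatistic("zero total variance")
    phi_ct = Va / V
    phi_sc = Vb / (Vb + Vc) if (Vb + Vc) != 0 else None
    phi_st = (Va + Vb) / V
    return phi_ct, phi_sc, phi_st


def amova(
    hap_table: HaplotypeTable,
    pmap: PopulationMap,
    spec: DistanceSpec | None = None,
) -> AmovaResult:
    """Full two-level AMOVA."""
    ss = amova_sums_of_squares(hap_table, pmap, spec)
    Va, Vb, Vc, pct, n_p, n_dp, n_tp = variance_components(ss)
    phi_ct, phi_sc, phi_st = phi_statistics(Va, Vb, Vc)
    return AmovaResult(
        ss_among_groups=ss["ss_among_groups"],
        ss_among_pops_within=ss["ss_among_pops_within"],
        ss_within=ss["ss_within"],
        ss_total=ss["ss_total"],
        df=ss["df"],
        Va=Va,
        Vb=Vb,
        Vc=Vc,
        pct=pct,
        phi_CT=phi_ct,
        phi_SC=phi_sc,
        phi_ST=phi_st,
        n_prime=n_p,
        n_dprime=n_dp,
        n_tprime=n_tp,
        negative_components=(Va < 0 or Vb < 0 or Vc < 0),
    )


# ---------------------------------------------------------------------------
# permutation significance
# ---------------------------------------------------------------------------


def _phi_from_counts(
    C: np.ndarray, group_of_pop: np.ndarray, d2: np.ndarray, G: int
) -> tuple[float | None, float | None, float | None]:
    """Fast numpy-only (Phi_CT, Phi_SC, Phi_ST) for the permutation loop.

    ``C`` is haplotype x population counts, ``group_of_pop[j]`` the group
    index of population j.  Mirrors amova()/variance_components(); the
    observed statistics always come from the full amova() path, so this
    helper is exercised against it on every permutation test run.
    """
    P = C.shape[1]
    pop_sizes = C.sum(axis=0)
    N = pop_sizes.sum()

    def unit_ss(c: np.ndarray) -> float:
        m = c.sum()
        return float(c @ d2 @ c) / (2.0 * m) if m else 0.0

    ss_total = unit_ss(C.sum(axis=1))
    ss_within = sum(unit_ss(C[:, j]) for j in range(P))
    group_sizes = np.zeros(G)
    ss_groups = 0.0
    sum_np2_by_group = np.zeros(G)
    for g in range(G):
        members = np.flatnonzero(group_of_pop == g)
        ss_groups += unit_ss(C[:, members].sum(axis=1))
        group_sizes[g] = pop_sizes[members].sum()
        sum_np2_by_group[g] = np.sum(pop_sizes[members] ** 2)
    df_a, df_b, df_c = G - 1, P - G, int(N) - P
    if df_a <= 0 or df_b <= 0 or df_c <= 0:
        return None, None, None

    Vc = ss_within / df_c
    sum_g = float(np.sum(sum_np2_by_group / group_sizes))
    n_prime = (N - sum_g) / df_b
    n_dprime = (sum_g - np.sum(pop_sizes**2) / N) / df_a
    n_tprime = (N - np.sum(group_sizes**2) / N) / df_a
    Vb = ((ss_groups - ss_within) / df_b - Vc) / n_prime
    Va = ((ss_total - ss_groups) / df_a - Vc - n_dprime * Vb) / n_tprime
    V = Va + Vb + Vc
    if V == 0:
        return None, None, None
    phi_ct = Va / V
    phi_sc = Vb / (Vb + Vc) if (Vb + Vc) != 0 else None
    phi_st = (Va + Vb) / V
    return phi_ct, phi_sc, phi_st


def amova_permutation_test(
    hap_table: HaplotypeTable,
    pmap: PopulationMap,
    spec: DistanceSpec | None = None,
    reps: int = 999,
    seed: int = 0,
) -> dict[str, float]:
    """Permutation p-values for Phi_ST, Phi_SC and Phi_CT (+1 correction).

    Phi_ST: accessions permuted among populations (sizes preserved).
    Phi_SC: accessions permuted among populations within their group.
    Phi_CT: whole populations permuted among groups (counts per group kept).
    """
    if reps < 99:
        raise InvalidArgument("reps must be >= 99")
    spec = spec or DistanceSpec()
    obs = amova(hap_table, pmap, spec)
    rng = np.random.default_rng(seed)

    pops = [p for p in pmap.populations if p in hap_table.populations]
    hap_ids = hap_table.haplotype_ids
    hap_index = {h: i for i, h in enumerate(hap_ids)}
    grouping = pmap.grouping()
    group_names = sorted({grouping[p] for p in pops})
    G = len(group_names)
    group_of_pop = np.array([group_names.index(grouping[p]) for p in pops])
    d2 = haplotype_distance_matrix(hap_table, spec)

    # accession-level label arrays
    hap_labels = np.array([hap_index[h] for h in hap_table.expand()])
    pop_labels = np.concatenate(
        [
            np.full(int(hap_table.counts[pop].sum()), j, dtype=int)
            for j, pop in enumerate(pops)
        ]
    )

    def counts_of(haps: np.ndarray, pops_arr: np.ndarray) -> np.ndarray:
        C = np.zeros((len(hap_ids), len(pops)), dtype=float)
        np.add.at(C, (haps, pops_arr), 1.0)
        return C

    hits = {"phi_ST": 0, "phi_SC": 0, "phi_CT": 0}
    base_counts = counts_of(hap_labels, pop_labels)
    pops_in_group = [np.flatnonzero(group_of_pop == g) for g in range(G)]

    for _ in range(reps):
        # ST: shuffle accessions across all populations
        perm = rng.permutation(hap_labels)
        _, _, phi_st = _phi_from_counts(counts_of(perm, pop_labels), group_of_pop, d2, G)
        if phi_st is not None and phi_st >= obs.phi_ST - 1e-12:
            hits["phi_ST"] += 1

        # SC: shuffle accessions within each group
        perm_sc = hap_labels.copy()
        for g in range(G):
            mask = np.isin(pop_labels, pops_in_group[g])
            perm_sc[mask] = rng.permutation(perm_sc[mask])
        _, phi_sc, _ = _phi_from_counts(counts_of(perm_sc, pop_labels), group_of_pop, d2, G)
        if phi_sc is not None and obs.phi_SC is not None and phi_sc >= obs.phi_SC - 1e-12:
            hits["phi_SC"] += 1

        # CT: shuffle whole populations among groups (group sizes in
        # numbers of populations preserved)
        phi_ct, _, _ = _phi_from_counts(
            base_counts, group_of_pop[rng.permutation(len(pops))], d2, G
        )
        if phi_ct is not None and phi_ct >= obs.phi_CT - 1e-12:
            hits["phi_CT"] += 1

    return {key: (v + 1) / (reps + 1) for key, v in hits.items()}
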