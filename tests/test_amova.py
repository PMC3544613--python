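"""Hierarchical AMOVA: published-table reproduction, oracle equivalence,
additivity, and permutation significance."""

import numpy as np
import pandas as pd
import pytest

import promopop as pp
from promopop.amova import haplotype_distance_matrix
from promopop.errors import InvalidArgument, InvalidHierarchy

# ---------------------------------------------------------------------------
# accession-level oracle: literal pairwise-sum computation
# ---------------------------------------------------------------------------


def accession_level_ss(table, pmap, d2):
    """Literal SS computation over materialised accession pairs."""
    hap_index = {h: i for i, h in enumerate(table.haplotype_ids)}
    pops = pmap.populations
    labels, pop_of = [], []
    for pop in pops:
        for hap in table.haplotype_ids:
            c = int(table.counts.at[hap, pop])
            labels.extend([hap_index[hap]] * c)
            pop_of.extend([pop] * c)
    labels = np.array(labels)
    pop_of = np.array(pop_of)
    grouping = pmap.grouping()

    def unit_ss(mask):
        idx = np.flatnonzero(mask)
        m = len(idx)
        total = 0.0
        for a in range(m):
            for b in range(a + 1, m):
                total += d2[labels[idx[a]], labels[idx[b]]]
        return total / m if m else 0.0

    ss_total = unit_ss(np.ones(len(labels), bool))
    ss_within = sum(unit_ss(pop_of == p) for p in pops)
    groups = sorted(set(grouping.values()))
    ss_group_units = sum(
        unit_ss(np.isin(pop_of, [p for p in pops if grouping[p] == g]))
        for g in groups
    )
    return ss_total, ss_within, ss_group_units - ss_within, ss_total - ss_group_units


def random_design(rng, max_total=60):
    """Random small two-level design with identity distances."""
    n_groups = int(rng.integers(2, 4))
    pops, spec_rows = [], []
    assignments = []
    hap_pool = [f"H{i}" for i in range(int(rng.integers(3, 8)))]
    counts = {}
    for g in range(n_groups):
        for p in range(int(rng.integers(1, 3)) + (1 if g == 0 else 0)):
            pop = f"G{g}P{p}"
            pops.append(pop)
            n = int(rng.integers(2, 8))
            draw = rng.multinomial(n, np.ones(len(hap_pool)) / len(hap_pool))
            counts[pop] = draw
            for i in range(n):
                assignments.append((f"{pop}_a{i}", pop, f"G{g}"))
    frame = pd.DataFrame(
        {p: counts[p] for p in pops}, index=hap_pool, dtype=int
    )
    frame = frame[frame.sum(axis=1) > 0]
    table = pp.HaplotypeTable(frame)
    return table, pp.PopulationMap(tuple(assignments))


# ---------------------------------------------------------------------------
# published-table reproduction
# ---------------------------------------------------------------------------


class TestPublishedTable:
    def test_sums_of_squares(self, fixture_table):
        table, pmap = fixture_table
        res = pp.amova(table, pmap)
        assert round(res.ss_among_groups, 3) == 5.913
        assert round(res.ss_among_pops_within, 3) == 14.729
        assert round(res.ss_within, 3) == 28.929
        assert round(res.ss_total, 3) == 49.571

    def test_degrees_of_freedom(self, fixture_table):
        table, pmap = fixture_table
        assert pp.amova(table, pmap).df == (1, 3, 107, 111)

    def test_variance_components_and_percentages(self, fixture_table):
        table, pmap = fixture_table
        res = pp.amova(table, pmap)
        assert round(res.Va, 3) == 0.022
        assert round(res.Vb, 3) == 0.207
        assert round(res.Vc, 3) == 0.270
        assert tuple(round(x, 1) for x in res.pct) == (4.4, 41.4, 54.2)

    def test_phi_st_consistent_with_variance_shares(self, fixture_table):
        """Phi_ST equals the among-population share of total variance
        (groups + populations-within-groups)."""
        table, pmap = fixture_table
        res = pp.amova(table, pmap)
        assert res.phi_ST == pytest.approx((res.pct[0] + res.pct[1]) / 100, abs=1e-12)
        assert round(res.phi_ST, 3) == 0.458

    def test_report_frame_shape(self, fixture_table):
        table, pmap = fixture_table
        frame = pp.amova(table, pmap).to_frame()
        assert list(frame["source"]) == [
            "Among groups",
            "Among populations within groups",
            "Within populations",
            "Total",
        ]
        assert frame["sum_of_squares"].tolist() == [5.913, 14.729, 28.929, 49.571]


# ---------------------------------------------------------------------------
# structural properties and oracle equivalence
# ---------------------------------------------------------------------------


class TestStructure:
    def test_distance_matrix_modes(self, tiny_alignment):
        aln, pmap = tiny_alignment
        table = pp.collapse_haplotypes(aln, pmap)
        ident = haplotype_distance_matrix(table, pp.DistanceSpec("identity"))
        assert np.array_equal(ident, 1.0 - np.eye(table.h))
        diff = haplotype_distance_matrix(table, pp.DistanceSpec("differences"))
        # Hap1 (ACGTACGTAC) vs Hap3 (AC--ACGTAC): one tandem indel = 1 unit
        i1 = table.haplotype_ids.index("Hap1")
        i3 = table.haplotype_ids.index("Hap3")
        assert diff[i1, i3] == 1.0
        with pytest.raises(InvalidArgument):
            pp.DistanceSpec("nonsense")

    def test_squared_differences_of_16_units_is_256(self):
        a = "A" * 40
        b = "G" * 16 + "A" * 24
        counts = pd.DataFrame({"P": [1, 1]}, index=["H1", "H2"])
        table = pp.HaplotypeTable(counts, {"H1": a, "H2": b})
        d2 = haplotype_distance_matrix(table, pp.DistanceSpec("differences"))
        assert d2[0, 1] == 256.0

    @pytest.mark.parametrize("seed", range(6))
    def test_block_computation_equals_accession_oracle(self, seed):
        """Block-wise SS equals the literal pairwise-sum oracle, and the
        decomposition is additive, on random designs."""
        rng = np.random.default_rng(seed)
        table, pmap = random_design(rng)
        d2 = haplotype_distance_matrix(table, pp.DistanceSpec("identity"))
        ss = pp.amova_sums_of_squares(table, pmap, pp.DistanceSpec("identity"))
        o_total, o_within, o_among_pops, o_among_groups = accession_level_ss(
            table, pmap, d2
        )
        assert ss["ss_total"] == pytest.approx(o_total, abs=1e-9)
        assert ss["ss_within"] == pytest.approx(o_within, abs=1e-9)
        assert ss["ss_among_pops_within"] == pytest.approx(o_among_pops, abs=1e-9)
        assert ss["ss_among_groups"] == pytest.approx(o_among_groups, abs=1e-9)
        # additivity and df sum
        assert ss["ss_within"] + ss["ss_among_pops_within"] + ss[
            "ss_among_groups"
        ] == pytest.approx(ss["ss_total"], abs=1e-9)
        assert sum(ss["df"][:3]) == ss["df"][3]

    def test_identity_closed_form(self, fixture_table):
        """Identity-mode per-population SS equals (n^2 - sum c^2) / (2n)."""
        table, pmap = fixture_table
        ss = pp.amova_sums_of_squares(table, pmap)
        expected = 0.0
        for pop in table.populations:
            c = table.population_counts(pop)
            n = c.sum()
            expected += (n**2 - np.sum(c**2)) / (2 * n)
        assert ss["ss_within"] == pytest.approx(expected, abs=1e-12)

    def test_monomorphic_shared_haplotype_all_zero(self):
        counts = pd.DataFrame({"P1": [3], "P2": [4]}, index=["H1"])
        pmap = pp.PopulationMap(
            tuple((f"a{i}", "P1", "g1") for i in range(3))
            + tuple((f"b{i}", "P2", "g2") for i in range(4))
        )
        ss = pp.amova_sums_of_squares(pp.HaplotypeTable(counts), pmap)
        assert ss["ss_total"] == ss["ss_within"] == 0.0

    def test_single_population_rejected(self):
        counts = pd.DataFrame({"P1": [2, 1]}, index=["H1", "H2"])
        pmap = pp.PopulationMap(tuple((f"a{i}", "P1", "g") for i in range(3)))
        with pytest.raises(InvalidHierarchy):
            pp.amova_sums_of_squares(pp.HaplotypeTable(counts), pmap)

    def test_fast_permutation_path_matches_full_amova(self, fixture_table):
        """The numpy path used inside the permutation loop reproduces the
        Phi statistics of the full AMOVA on the observed data."""
        from promopop.amova import _phi_from_counts

        table, pmap = fixture_table
        res = pp.amova(table, pmap)
        pops = table.populations
        group_names = sorted({pmap.group_of(p) for p in pops})
        group_of_pop = np.array(
            [group_names.index(pmap.group_of(p)) for p in pops]
        )
        d2 = haplotype_distance_matrix(table)
        ct, sc, st = _phi_from_counts(
            table.counts.to_numpy(dtype=float), group_of_pop, d2, 2
        )
        assert ct == pytest.approx(res.phi_CT, abs=1e-12)
        assert sc == pytest.approx(res.phi_SC, abs=1e-12)
        assert st == pytest.approx(res.phi_ST, abs=1e-12)

    def test_phi_boundaries(self):
        assert pp.phi_statistics(0, 0, 1) == (0, 0, 0)
        ct, sc, st = pp.phi_statistics(1, 0, 0)
        assert ct == 1 and st == 1 and sc is None


class TestPermutationTest:
    def test_deterministic_under_seed(self, fixture_table):
        table, pmap = fixture_table
        p1 = pp.amova_permutation_test(table, pmap, reps=99, seed=3)
        p2 = pp.amova_permutation_test(table, pmap, reps=99, seed=3)
        assert p1 == p2

    def test_perfect_differentiation_floors_p(self):
        """Disjoint haplotype sets per population: phi_ST at its maximum,
        permutation p at (or near) the 1/(reps+1) floor."""
        counts = pd.DataFrame(np.eye(4, dtype=int) * 6, index=[f"H{i}" for i in range(4)],
                              columns=["P1", "P2", "P3", "P4"])
        pmap = pp.PopulationMap(
            tuple(
                (f"{pop}_a{i}", pop, "g1" if pop in ("P1", "P2") else "g2")
                for pop in ("P1", "P2", "P3", "P4")
                for i in range(6)
            )
        )
        p = pp.amova_permutation_test(
            pp.HaplotypeTable(counts), pmap, reps=99, seed=1
        )
        assert p["phi_ST"] <= 5 / 100  # floor plus possible ties

    def test_panmictic_null_not_anticonservative(self):
        """On exchangeable data the phi_ST permutation p is not smaller
        than nominal more often than Monte-Carlo noise allows."""
        rng = np.random.default_rng(17)
        rejections = 0
        n_datasets = 60
        for _ in range(n_datasets):
            labels = rng.integers(0, 4, size=24)
            counts = pd.DataFrame(
                {
                    "P1": np.bincount(labels[:8], minlength=4),
                    "P2": np.bincount(labels[8:16], minlength=4),
                    "P3": np.bincount(labels[16:], minlength=4),
                },
                index=[f"H{i}" for i in range(4)],
            )
            pmap = pp.PopulationMap(
                tuple((f"a{i}", "P1", "g1") for i in range(8))
                + tuple((f"b{i}", "P2", "g1") for i in range(8))
                + tuple((f"c{i}", "P3", "g2") for i in range(8))
            )
            p = pp.amova_permutation_test(
                pp.HaplotypeTable(counts), pmap, reps=99,
                seed=int(rng.integers(2**31)),
            )
            rejections += p["phi_ST"] <= 0.05
        rate = rejections / n_datasets
        se = np.sqrt(0.05 * 0.95 / n_datasets)
        assert rate <= 0.05 + 3 * se
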