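"""Diversity and neutrality statistics against independent oracles.

Oracles used here are deliberately separate code paths: exact-rational
(Fraction) transcriptions of the coefficient formulas, brute-force all-pairs
difference counting on expanded accession lists, and tskit's site-statistics
engine on msprime genealogies.
"""

from fractions import Fraction

import numpy as np
import pytest

import promopop as pp
from promopop.errors import InvalidArgument, UndefinedStatistic

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def tajima_coefficients_fraction(n: int) -> dict:
    """Exact-rational transcription of the Tajima (1989) coefficients."""
    a1 = sum(Fraction(1, i) for i in range(1, n))
    a2 = sum(Fraction(1, i * i) for i in range(1, n))
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2, n) / a1 + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def fu_li_coefficients_fraction(n: int) -> tuple[Fraction, Fraction]:
    """Exact-rational transcription of the corrected F* variance
    coefficients (Simonsen-Churchill-Aquadro form)."""
    a_n = sum(Fraction(1, i) for i in range(1, n))
    b_n = sum(Fraction(1, i * i) for i in range(1, n))
    a_n1 = a_n + Fraction(1, n)
    v = (
        Fraction(2 * n**3 + 110 * n**2 - 255 * n + 153, 9 * n**2 * (n - 1))
        + Fraction(2 * (n - 1), n**2) * a_n
        - Fraction(8, n) * b_n
    ) / (a_n**2 + b_n)
    u = (Fraction(4 * n**2 + 19 * n + 3, 3 * n * (n - 1)) - Fraction(12 * (n + 1), 3 * n * (n - 1)) * a_n1) / a_n - v
    return u, v


def brute_force_pi_k(seqs: list[str], counts: list[int]) -> tuple[float, float]:
    """All-pairs complete-deletion oracle over the expanded accession list."""
    expanded = [s for s, c in zip(seqs, counts) for _ in range(c)]
    n = len(expanded)
    cols = [
        i
        for i in range(len(expanded[0]))
        if all(s[i] not in "-N" for s in expanded)
    ]
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += sum(expanded[i][c] != expanded[j][c] for c in cols)
    k = total / (n * (n - 1) / 2)
    return k / len(cols), k


def random_alignment(rng, n, length, with_gaps=False):
    chars = list("ACGT-") if with_gaps else list("ACGT")
    p = [0.3, 0.3, 0.15, 0.15, 0.1] if with_gaps else [0.3, 0.3, 0.2, 0.2]
    return ["".join(rng.choice(chars, size=length, p=p)) for _ in range(n)]


# ---------------------------------------------------------------------------
# haplotype diversity
# ---------------------------------------------------------------------------


class TestHaplotypeDiversity:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((19, 1), 0.100),  # P1
            ((6, 4, 7, 4), 0.771),  # P2
            ((1, 17, 1), 0.205),  # P3
            ((7, 1, 1, 1, 12, 1, 1, 1, 1), 0.732),  # P4
            ((2, 5, 4, 12, 2, 1), 0.742),  # P5
        ],
    )
    def test_published_population_values(self, counts, expected):
        assert round(pp.haplotype_diversity(counts), 3) == expected

    def test_monomorphic_is_zero(self):
        assert pp.haplotype_diversity((5,)) == 0.0

    def test_n_below_two_undefined(self):
        with pytest.raises(UndefinedStatistic):
            pp.haplotype_diversity((1,))

    def test_counts_match_collapse(self, synthetic_study):
        """Hd from the count table equals Hd computed from collapsing the
        raw alignment (pipeline consistency)."""
        aln, pmap, _ = synthetic_study
        table = pp.collapse_haplotypes(aln, pmap)
        from_counts = pp.haplotype_diversity(table.pooled_counts())
        seq_counts = {}
        for _, seq in aln.records:
            seq_counts[seq] = seq_counts.get(seq, 0) + 1
        assert from_counts == pytest.approx(
            pp.haplotype_diversity(tuple(seq_counts.values())), abs=1e-15
        )


# ---------------------------------------------------------------------------
# pi and k
# ---------------------------------------------------------------------------


class TestNucleotideDiversity:
    def test_identical_sequences_zero(self):
        aln = pp.AlignmentSet((("a", "ACGT"), ("b", "ACGT")))
        assert pp.nucleotide_diversity(aln) == (0.0, 0.0)

    def test_three_sequence_hand_case(self):
        """Pairwise differences {1, 1, 2} on complete length 10 gives
        k = 4/3 and pi = 0.1333."""
        aln = pp.AlignmentSet(
            (
                ("a", "AAAAAAAAAA"),
                ("b", "AAAAAAAAAC"),
                ("c", "AAAAAAAACC"),
            )
        )
        pi, k = pp.nucleotide_diversity(aln)
        assert k == pytest.approx(4 / 3, abs=1e-12)
        assert pi == pytest.approx(4 / 30, abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        """pi/k equal the all-pairs oracle to 1e-12 on random instances
        of up to 30 sequences, gaps included."""
        rng = np.random.default_rng(seed)
        h = int(rng.integers(2, 6))
        seqs = random_alignment(rng, h, 40, with_gaps=seed % 2 == 0)
        counts = rng.integers(1, 8, size=h).tolist()
        while sum(counts) > 30:
            counts[int(np.argmax(counts))] -= 1
        import pandas as pd

        # ensure distinct haplotype sequences for the table container
        if len(set(seqs)) != len(seqs):
            return
        table = pp.HaplotypeTable(
            pd.DataFrame({"P": counts}, index=[f"H{i}" for i in range(h)]),
            dict(zip([f"H{i}" for i in range(h)], seqs)),
        )
        pi, k = pp.nucleotide_diversity(table, "complete")
        pi_o, k_o = brute_force_pi_k(seqs, counts)
        assert k == pytest.approx(k_o, abs=1e-12)
        assert pi == pytest.approx(pi_o, abs=1e-12)


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------


class TestTajimasD:
    def test_zero_segregating_sites_is_missing(self):
        assert pp.tajimas_d(0, 0.0, 10) is None

    def test_small_n_rejected(self):
        with pytest.raises(UndefinedStatistic):
            pp.tajimas_d(5, 1.0, 3)

    @pytest.mark.parametrize("n", [4, 5, 10, 20, 112])
    def test_coefficients_match_rational_oracle(self, n):
        coef = pp.tajima_coefficients(n)
        oracle = tajima_coefficients_fraction(n)
        for name in ("a1", "a2", "b1", "b2", "c1", "c2", "e1", "e2"):
            assert getattr(coef, name) == pytest.approx(
                float(oracle[name]), abs=1e-10
            )

    def test_full_statistic_against_stepwise_oracle(self):
        """n=10 constructed alignment: D recomputed coefficient by
        coefficient with exact rationals matches to 1e-10."""
        rng = np.random.default_rng(42)
        seqs = random_alignment(rng, 10, 60)
        aln = pp.AlignmentSet(tuple((f"r{i}", s) for i, s in enumerate(seqs)))
        S, _, _ = pp.mutation_counts(aln)
        _, k = pp.nucleotide_diversity(aln)
        d = pp.tajimas_d(S, k, 10)
        o = tajima_coefficients_fraction(10)
        expected = (k - S / float(o["a1"])) / np.sqrt(
            float(o["e1"]) * S + float(o["e2"]) * S * (S - 1)
        )
        assert d == pytest.approx(expected, abs=1e-10)

    def test_coefficient_monotonicity_and_positivity(self):
        a_prev = 0.0
        for n in range(4, 60):
            coef = pp.tajima_coefficients(n)
            assert coef.a1 > a_prev
            assert coef.e1 > 0 and coef.e2 > 0
            a_prev = coef.a1

    def test_balancing_vs_star_signatures(self):
        """Two deep clades -> D > 0; star-like excess singletons -> D < 0."""
        base = "A" * 40
        clade2 = "G" * 12 + "A" * 28
        two_clade = [base] * 5 + [clade2] * 5
        aln = pp.AlignmentSet(tuple((f"r{i}", s) for i, s in enumerate(two_clade)))
        S, _, _ = pp.mutation_counts(aln)
        _, k = pp.nucleotide_diversity(aln)
        assert pp.tajimas_d(S, k, 10) > 0

        star = [base] + [
            base[:i] + "G" + base[i + 1 :] for i in range(9)
        ]
        aln = pp.AlignmentSet(tuple((f"r{i}", s) for i, s in enumerate(star)))
        S, _, _ = pp.mutation_counts(aln)
        _, k = pp.nucleotide_diversity(aln)
        assert pp.tajimas_d(S, k, 10) < 0

    def test_matches_tskit_on_msprime_genealogies(self):
        """Independent cross-check: our D from (S, k) equals tskit's
        site-mode Tajima's D on msprime-simulated samples."""
        msprime = pytest.importorskip("msprime")
        for seed in (1, 2, 3):
            ts = msprime.sim_ancestry(
                samples=10, ploidy=1, sequence_length=1000, random_seed=seed
            )
            ts = msprime.sim_mutations(
                ts, rate=5e-3, random_seed=seed, model=msprime.BinaryMutationModel()
            )
            if ts.num_sites == 0:
                continue
            n = ts.num_samples
            geno = ts.genotype_matrix()  # sites x samples
            seqs = [
                "".join("ACGT"[geno[s, j]] for s in range(ts.num_sites))
                for j in range(n)
            ]
            aln = pp.AlignmentSet(tuple((f"s{j}", s) for j, s in enumerate(seqs)))
            S, _, _ = pp.mutation_counts(aln)
            _, k = pp.nucleotide_diversity(aln)
            ours = pp.tajimas_d(S, k, n)
            assert ours == pytest.approx(float(ts.Tajimas_D()), abs=1e-8)


# ---------------------------------------------------------------------------
# Fu & Li's F*
# ---------------------------------------------------------------------------


class TestFuLiFStar:
    def test_no_mutations_is_missing(self):
        assert pp.fu_li_f_star(0, 0, 0.0, 10) is None

    @pytest.mark.parametrize("n", [4, 5, 8, 10, 20, 50, 112])
    def test_coefficients_match_rational_oracle(self, n):
        coef = pp.fu_li_coefficients(n)
        u, v = fu_li_coefficients_fraction(n)
        assert coef.u_F == pytest.approx(float(u), abs=1e-12)
        assert coef.v_F == pytest.approx(float(v), abs=1e-12)

    def test_variance_coefficients_positive(self):
        for n in range(4, 120):
            coef = pp.fu_li_coefficients(n)
            assert coef.u_F > 0 and coef.v_F > 0

    def test_star_like_singleton_excess_is_negative(self):
        base = "A" * 40
        star = [base] + [base[:i] + "G" + base[i + 1 :] for i in range(9)]
        aln = pp.AlignmentSet(tuple((f"r{i}", s) for i, s in enumerate(star)))
        S, eta, eta_s = pp.mutation_counts(aln)
        _, k = pp.nucleotide_diversity(aln)
        assert eta_s == eta  # every mutation private to one sequence
        assert pp.fu_li_f_star(eta, eta_s, k, 10) < 0

    def test_no_singletons_large_k_is_positive(self):
        base = "A" * 40
        clade2 = "G" * 12 + "A" * 28
        aln = pp.AlignmentSet(
            tuple((f"r{i}", s) for i, s in enumerate([base] * 5 + [clade2] * 5))
        )
        S, eta, eta_s = pp.mutation_counts(aln)
        _, k = pp.nucleotide_diversity(aln)
        assert eta_s == 0
        assert pp.fu_li_f_star(eta, eta_s, k, 10) > 0

    def test_invalid_eta_ordering(self):
        with pytest.raises(InvalidArgument):
            pp.fu_li_f_star(2, 5, 1.0, 10)


# ---------------------------------------------------------------------------
# coalescent null and p-values
# ---------------------------------------------------------------------------


class TestNeutralCoalescent:
    def test_mean_d_near_zero_under_neutrality(self):
        """2000 neutral genealogies (n=20, S=20): mean D within Monte-Carlo
        error of its near-zero conditional expectation."""
        rng = np.random.default_rng(2024)
        ds = []
        for _ in range(2000):
            k, _, _ = pp.simulate_neutral_summaries(20, 20, rng)
            ds.append(pp.tajimas_d(20, k, 20))
        ds = np.array(ds)
        sem = ds.std(ddof=1) / np.sqrt(len(ds))
        # |E[D | S]| for n=20 is below ~0.05; allow 3 MC standard errors
        assert abs(ds.mean()) <= 0.05 + 3 * sem

    def test_pvalue_deterministic_under_seed(self):
        p1 = pp.neutrality_pvalue("D", -1.8, 20, 10, reps=200, seed=5)
        p2 = pp.neutrality_pvalue("D", -1.8, 20, 10, reps=200, seed=5)
        assert p1 == p2

    def test_extreme_statistic_hits_floor(self):
        p = pp.neutrality_pvalue("D", 50.0, 20, 10, reps=200, seed=5)
        assert p == pytest.approx(1 / 201)

    def test_null_pvalues_calibrated(self):
        """Statistics drawn from their own null reject at close to the
        nominal 5% rate."""
        rng = np.random.default_rng(99)
        reps, n, S, n_datasets = 199, 20, 10, 200
        rejections = 0
        for _ in range(n_datasets):
            k, _, _ = pp.simulate_neutral_summaries(n, S, rng)
            d = pp.tajimas_d(S, k, n)
            p = pp.neutrality_pvalue(
                "D", d, n, S, reps=reps, seed=int(rng.integers(2**31))
            )
            rejections += p <= 0.05
        rate = rejections / n_datasets
        se = np.sqrt(0.05 * 0.95 / n_datasets)
        assert rate <= 0.05 + 3 * se  # valid (possibly conservative) test

    def test_s_zero_undefined(self):
        with pytest.raises(UndefinedStatistic):
            pp.neutrality_pvalue("D", 0.0, 20, 0, reps=200, seed=1)
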