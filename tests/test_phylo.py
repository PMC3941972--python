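"""Fragment collection, distances, neighbor joining and age conversion."""

import numpy as np
import pytest

import te_strain_scan as ts
from te_strain_scan._seq import mutate, random_dna
from te_strain_scan.phylo import GAP, AgeModel


class TestCollectFragments:
    def test_planted_full_copies_span_consensus(self, rng):
        cons = random_dna(800, rng)
        genome = (random_dna(2000, rng) + cons + random_dna(2000, rng)
                  + ts.revcomp(cons) + random_dna(2000, rng) + cons
                  + random_dna(2000, rng))
        frags = ts.collect_fragments(genome, cons)
        assert len(frags) == 3
        for h in frags.hits:
            assert (h.cons_start, h.cons_end) == (0, 800)
            assert h.identity == 1.0

    def test_short_fragment_filtered_by_min_length(self, rng):
        cons = random_dna(800, rng)
        genome = random_dna(2000, rng) + cons[100:180] + random_dna(2000, rng)
        assert len(ts.collect_fragments(genome, cons, min_length=100)) == 0
        assert len(ts.collect_fragments(genome, cons, min_length=60)) == 1

    def test_copy_count_recovered_error_free(self, small_family, small_genomes):
        genome = small_genomes["A"]
        frags = ts.collect_fragments(genome.sequence, small_family.consensus,
                                     min_length=100)
        expected = sum(1 for i in genome.insertions
                       if i.end - i.start >= 100)
        assert len(frags) == expected

    def test_tir_only_hits_excluded(self, rng):
        tir = random_dna(235, rng)
        cons = tir + random_dna(1000, rng) + ts.revcomp(tir)
        # a genome containing just one stray TIR copy plus one full copy
        genome = (random_dna(1500, rng) + tir + random_dna(1500, rng)
                  + cons + random_dna(1500, rng))
        without = ts.collect_fragments(genome, cons,
                                       exclude_tir=(235, len(cons) - 235))
        assert len(without) == 1
        assert without.hits[0].cons_end - without.hits[0].cons_start > 1000


class TestPairwiseDistance:
    def _frag(self, rows):
        arr = np.array(rows, dtype=np.uint8)
        return arr

    def test_identical_fragments_zero(self):
        rows = self._frag([[0, 1, 2, 3] * 25] * 2)
        ids, d, sat = ts.pairwise_distance(rows, correction="none")
        assert d[0, 1] == 0.0 and not sat.any()

    def test_jc_closed_form(self):
        """p = 0.10 -> d = -(3/4) ln(1 - 4(0.10)/3) = 0.10732."""
        base = np.tile(np.array([0, 1, 2, 3], np.uint8), 25)
        other = base.copy()
        other[:10] = (other[:10] + 1) % 4  # exactly 10 mismatches in 100
        ids, d, _ = ts.pairwise_distance(np.vstack([base, other]))
        assert d[0, 1] == pytest.approx(0.1073256, abs=1e-6)

    def test_jc_at_least_p(self, rng):
        for _ in range(10):
            a = rng.integers(0, 4, 200).astype(np.uint8)
            b = a.copy()
            k = int(rng.integers(1, 100))
            b[:k] = (b[:k] + rng.integers(1, 4, k)) % 4
            _, dp, _ = ts.pairwise_distance(np.vstack([a, b]), "none")
            _, dj, satur = ts.pairwise_distance(np.vstack([a, b]), "jc")
            if not satur[0, 1]:
                assert dj[0, 1] >= dp[0, 1]

    def test_symmetry_zero_diagonal(self, rng):
        base = rng.integers(0, 4, 120).astype(np.uint8)
        rows = np.vstack([base] * 4)
        for i in range(1, 4):
            k = 10 * i
            rows[i, :k] = (rows[i, :k] + rng.integers(1, 4, k)) % 4
        _, d, _ = ts.pairwise_distance(rows, "none")
        assert (np.diag(d) == 0).all()
        assert d == pytest.approx(d.T)

    def test_gap_columns_skipped_and_disjoint_nan(self):
        a = np.array([0] * 50 + [GAP] * 50, np.uint8)
        b = np.array([GAP] * 50 + [1] * 50, np.uint8)
        c = np.array([0] * 100, np.uint8)
        _, d, _ = ts.pairwise_distance(np.vstack([a, b, c]), "none")
        assert np.isnan(d[0, 1])
        assert d[0, 2] == 0.0
        assert d[1, 2] == 1.0 or np.isnan(d[1, 2])  # p=1 -> saturated NaN

    def test_saturated_pair_flagged(self):
        a = np.zeros(100, np.uint8)
        b = np.ones(100, np.uint8)
        _, d, sat = ts.pairwise_distance(np.vstack([a, b]))
        assert sat[0, 1] and np.isnan(d[0, 1])


class TestNeighborJoining:
    # additive matrix of tree ((A:1,B:2):1,(C:3,D:4))
    IDS = ["A", "B", "C", "D"]
    D = np.array([[0, 3, 5, 6],
                  [3, 0, 6, 7],
                  [5, 6, 0, 7],
                  [6, 7, 7, 0]], float)

    def test_additive_matrix_recovered_exactly(self):
        tree = ts.nj_tree(self.IDS, self.D)
        tips = {t.name: t.length for t in tree.tips()}
        assert tips == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 4})
        tt = tree.tip_tip_distances(self.IDS)
        assert np.asarray(tt.data) == pytest.approx(self.D)

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 5, 9], [5, 0, 8], [9, 8, 0]], float)
        tree = ts.nj_tree(["A", "B", "C"], d)
        tips = {t.name: t.length for t in tree.tips()}
        # a = (dAB + dAC - dBC)/2 etc.
        assert tips["A"] == pytest.approx((5 + 9 - 8) / 2)
        assert tips["B"] == pytest.approx((5 + 8 - 9) / 2)
        assert tips["C"] == pytest.approx((9 + 8 - 5) / 2)

    def test_taxon_order_permutation_invariant(self):
        perm = [2, 0, 3, 1]
        tree2 = ts.nj_tree([self.IDS[i] for i in perm],
                           self.D[np.ix_(perm, perm)])
        tt = tree2.tip_tip_distances(self.IDS)
        assert np.asarray(tt.data) == pytest.approx(self.D)

    def test_incomplete_matrix_rejected(self):
        d = self.D.copy()
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(ValueError):
            ts.nj_tree(self.IDS, d)


class TestTerminalBranches:
    def test_hand_parsed_newick(self):
        got = dict(ts.terminal_branch_lengths(
            "(A:0.1,B:0.2,(C:0.3,D:0.4):0.05);"))
        assert got == pytest.approx({"A": 0.1, "B": 0.2, "C": 0.3, "D": 0.4})

    def test_star_tree_equal_lengths(self):
        got = ts.terminal_branch_lengths("(A:0.5,B:0.5,C:0.5,D:0.5);")
        assert all(L == 0.5 for _, L in got)

    def test_write_read_round_trip(self):
        tree = ts.nj_tree(TestNeighborJoining.IDS, TestNeighborJoining.D)
        import io
        buf = io.StringIO()
        tree.write(buf)
        again = ts.terminal_branch_lengths(buf.getvalue())
        assert dict(again) == pytest.approx(
            dict(ts.terminal_branch_lengths(tree)))

    def test_missing_length_rejected(self):
        with pytest.raises(ValueError):
            ts.terminal_branch_lengths("(A,B,(C,D));")


class TestAges:
    def test_published_clock_arithmetic(self):
        """0.10 subs/bp at 1.45e-9 subs/bp/gen and 10 gen/yr is ~7 My."""
        age = ts.branch_length_to_age(0.10, AgeModel(1.45e-9, 10))
        assert age == pytest.approx(6.896552e6, rel=1e-6)
        assert round(age / 1e6) == 7

    @pytest.mark.parametrize("L,expected", [
        (0.0, 0.0), (0.029, 2.0e6),
    ])
    def test_linear_formula(self, L, expected):
        assert ts.branch_length_to_age(L, AgeModel(1.45e-9, 10)) == \
            pytest.approx(expected, rel=0.01)

    def test_doubling_clock_halves_ages(self):
        m1, m2 = AgeModel(1.45e-9, 10), AgeModel(2.9e-9, 10)
        assert ts.branch_length_to_age(0.2, m1) == \
            pytest.approx(2 * ts.branch_length_to_age(0.2, m2))

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            ts.branch_length_to_age(-0.1)


class TestAgeDistribution:
    def test_equal_lengths_single_bin(self):
        out = ts.age_distribution([1e6] * 10, bins=5)
        assert (out["counts"] > 0).sum() == 1
        assert out["counts"].sum() == 10

    def test_counts_sum_to_leaves(self, rng):
        ages = rng.uniform(0, 1e7, 40)
        out = ts.age_distribution(ages, bins=12)
        assert out["counts"].sum() == 40

    def test_two_epoch_history_is_bimodal(self, rng):
        """Recent burst (0.5% divergence) on a background of an old
        cohort (~15%): one mode near zero age, one near the old cohort's
        clock age."""
        cons = random_dna(1200, rng)
        pieces = [random_dna(1500, rng)]
        for _ in range(8):  # recent burst
            pieces += [mutate(cons, 0.005, rng), random_dna(1500, rng)]
        for _ in range(6):  # ancient cohort
            pieces += [mutate(cons, 0.15, rng), random_dna(1500, rng)]
        genome = "".join(pieces)
        frags = ts.collect_fragments(genome, cons, min_length=100)
        assert len(frags) == 14
        result = ts.date_fragments(frags)
        ages = np.sort(result.ages_years)
        young = (ages < 2e6).sum()
        old = (ages > 5e6).sum()
        assert young >= 7 and old >= 5
        assert ((ages >= 2e6) & (ages <= 5e6)).sum() <= 1
        # old cohort centers near its simulated divergence converted by
        # the clock: JC(0.15) ~ 0.167 -> ~11.5 My
        assert np.median(ages[ages > 5e6]) == pytest.approx(11.5e6, rel=0.35)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ts.age_distribution([])
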