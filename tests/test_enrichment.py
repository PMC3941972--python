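"""Read assignment, counting, normalization and the chi-squared screen,
checked against exhaustive-scan and hand-formula oracles."""

import numpy as np
import pytest

import te_strain_scan as ts
from te_strain_scan._seq import encode, random_dna
from te_strain_scan.enrichment import chisq_enrichment, coverage_estimate


def brute_force_best(read: str, library: dict[str, str],
                     min_aligned_fraction: float = 0.5):
    """Exhaustive gapless scan over every family, strand and offset —
    the independent oracle for the seeded assigner (exact for
    substitution-only reads).  Same constraints and tie rules: aligned
    fraction floor, then identity, aligned length, lexicographic id."""
    n = len(read)
    best = None
    for fid in sorted(library):
        cons = encode(library[fid])
        L = len(cons)
        for strand, rcodes in (("+", encode(read)), ("-", encode(ts.revcomp(read)))):
            for offset in range(-n + 1, L):
                ostart, cstart = max(0, -offset), max(0, offset)
                length = min(n - ostart, L - cstart)
                if length < min_aligned_fraction * n:
                    continue
                m = int(np.count_nonzero(
                    rcodes[ostart:ostart + length] == cons[cstart:cstart + length]))
                key = (m / length, length)
                if best is None or key > best[0]:
                    best = (key, fid, strand, cstart)
    return best


class TestIndex:
    def test_single_consensus_full_length_kmer(self):
        lib = ts.RepeatLibrary({"X": random_dna(20, np.random.default_rng(0))})
        idx = ts.build_index(lib, k=20)
        assert len(idx) == 2  # one entry per strand

    def test_absent_kmer_empty(self, small_index):
        assert small_index.lookup("A" * 15) == ()

    def test_planted_kmer_positions_match_naive_scan(self, small_family):
        cons = small_family.consensus
        idx = ts.build_index(ts.RepeatLibrary({"POLY": cons}), k=15)
        kmer = cons[500:515]
        naive = [i for i in range(len(cons) - 14) if cons[i:i + 15] == kmer]
        got = sorted(p for fid, p, s in idx.lookup(kmer) if s == "+")
        assert got == naive

    def test_k_larger_than_consensus_rejected(self):
        lib = ts.RepeatLibrary({"X": "ACGTACGTACGT"})
        with pytest.raises(ValueError):
            ts.build_index(lib, k=15)


class TestAssignRead:
    def test_exact_substring(self, small_family, small_index):
        read = small_family.consensus[300:400]
        a = ts.assign_read(read, small_index)
        assert (a.family_id, a.strand, a.start) == ("POLY", "+", 300)
        assert a.identity == 1.0 and a.aligned_length == 100

    def test_reverse_complement_maps_minus_strand(self, small_family, small_index):
        read = ts.revcomp(small_family.consensus[300:400])
        a = ts.assign_read(read, small_index)
        assert (a.family_id, a.strand, a.start) == ("POLY", "-", 300)
        assert a.identity == 1.0
        assert a.aligned_sequence == small_family.consensus[300:400]

    def test_closer_family_wins(self, rng):
        cons_a = random_dna(500, rng)
        cons_b = ts.mutated = ts.revcomp(cons_a)  # unrelated enough
        lib = ts.RepeatLibrary({"A": cons_a, "B": random_dna(500, rng)})
        idx = ts.build_index(lib, k=15)
        read = list(cons_a[100:200])
        for pos in (5, 25, 45, 65, 85):  # 5 substitutions vs A
            read[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[pos]]
        a = ts.assign_read("".join(read), idx)
        assert a.family_id == "A"
        assert a.identity == pytest.approx(0.95)

    def test_low_identity_unassigned(self, small_index, rng):
        a = ts.assign_read(random_dna(100, rng), small_index)
        assert not a.assigned

    def test_agrees_with_exhaustive_oracle(self, rng):
        """On libraries of <=5 families and substitution-only reads whose
        best and second-best identities differ, the seeded assigner
        matches an exhaustive all-offset scan."""
        library = {f"fam{i}": random_dna(400, rng) for i in range(5)}
        idx = ts.build_index(ts.RepeatLibrary(library), k=15)
        checked = 0
        for _ in range(60):
            fid = f"fam{rng.integers(5)}"
            start = int(rng.integers(0, 300))
            read = list(library[fid][start:start + 100])
            for pos in rng.choice(100, size=int(rng.integers(0, 9)),
                                  replace=False):
                read[pos] = "ACGT"[int(rng.integers(4))]
            read = "".join(read)
            if rng.random() < 0.5:
                read = ts.revcomp(read)
            (key, ofid, ostrand, ostart) = brute_force_best(read, library)
            a = ts.assign_read(read, idx, min_identity=0.85)
            assert a.assigned
            assert (a.identity, a.aligned_length) == pytest.approx(key)
            if key[0] == 1.0 or a.identity > 0.9:
                assert (a.family_id, a.strand, a.start) == (ofid, ostrand, ostart)
            checked += 1
        assert checked == 60

    def test_matches_smith_waterman_identity(self, rng):
        """Local Smith-Waterman (Biopython) confirms the gapless identity
        on substitution-only instances."""
        from Bio import Align
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -10
        aligner.extend_gap_score = -10
        cons = random_dna(400, rng)
        idx = ts.build_index(ts.RepeatLibrary({"F": cons}), k=15)
        for _ in range(10):
            start = int(rng.integers(0, 300))
            read = list(cons[start:start + 100])
            for pos in rng.choice(100, size=4, replace=False):
                read[pos] = "ACGT"[int(rng.integers(4))]
            read = "".join(read)
            a = ts.assign_read(read, idx)
            score = aligner.align(cons, read).score
            # score = matches - mismatches within the aligned span
            matches = round(a.identity * a.aligned_length)
            assert score >= 2 * matches - a.aligned_length


class TestCounting:
    def _assignments(self):
        mk = lambda fid, n: [ts.ReadAssignment(f"r{i}", fid, 0, "+", 1.0, 100)
                             for i in range(n)]  # noqa: E731
        return {"A": mk("X", 3) + mk("Y", 1) +
                     [ts.ReadAssignment("u", None, 0, ".", 0.0, 0)],
                "B": mk("X", 1)}

    def test_counts_and_recount_oracle(self):
        table = ts.count_table(self._assignments(), {"A": 100, "B": 100})
        assert table.counts.at["A", "X"] == 3
        assert table.counts.at["A", "Y"] == 1
        assert table.counts.at["B", "X"] == 1
        assert table.counts.at["B", "Y"] == 0
        # unassigned reads excluded
        assert table.counts.loc["A"].sum() == 4

    def test_empty_assignments_zero_table(self):
        table = ts.count_table({"A": [], "B": []}, {"A": 10, "B": 10},
                               families=["X"])
        assert (table.counts.to_numpy() == 0).all()

    def test_missing_denominator_rejected(self):
        with pytest.raises(ValueError):
            ts.count_table(self._assignments(), {"A": 100})

    @pytest.mark.parametrize("r,M,expected", [
        (500, 1_000_000, 500.0),
        (0, 1_000_000, 0.0),
        (137, 24_300_000, 1e6 * 137 / 24_300_000),
    ])
    def test_normalize_arithmetic(self, r, M, expected):
        table = ts.count_table(
            {"A": [ts.ReadAssignment(f"r{i}", "X", 0, "+", 1.0, 100)
                   for i in range(r)]}, {"A": M}, families=["X"])
        assert ts.normalize(table).at["A", "X"] == pytest.approx(expected)

    def test_normalization_scale_invariance(self):
        t1 = ts.count_table(
            {"A": [ts.ReadAssignment(f"r{i}", "X", 0, "+", 1.0, 100)
                   for i in range(50)]}, {"A": 1000}, families=["X"])
        t2 = ts.count_table(
            {"A": [ts.ReadAssignment(f"r{i}", "X", 0, "+", 1.0, 100)
                   for i in range(100)]}, {"A": 2000}, families=["X"])
        assert ts.normalize(t1).at["A", "X"] == ts.normalize(t2).at["A", "X"]


class TestFoldAndChisq:
    def _table(self, r1, r2, m1=1_000_000, m2=1_000_000):
        mk = lambda fid, n: [ts.ReadAssignment(f"r{i}", fid, 0, "+", 1.0, 100)
                             for i in range(n)]  # noqa: E731
        return ts.count_table({"A": mk("X", r1), "B": mk("X", r2)},
                              {"A": m1, "B": m2}, families=["X"])

    def test_fold_ratio_examples(self):
        assert ts.fold_enrichment(self._table(50, 50), "X", ("A", "B")) == 1.0
        assert ts.fold_enrichment(self._table(270, 10), "X", ("A", "B")) == \
            pytest.approx(27.0)
        assert ts.fold_enrichment(self._table(270, 10), "X", ("B", "A")) == \
            pytest.approx(1 / 27.0)
        assert np.isnan(ts.fold_enrichment(self._table(0, 0), "X", ("A", "B")))

    def test_chisq_equal_proportions_zero(self):
        stat, p = chisq_enrichment(50, 1000, 100, 2000)
        assert stat == 0.0 and p == 1.0

    def test_chisq_hand_example(self):
        """[[10, 990], [1, 999]]: Pearson formula by hand gives 7.404."""
        stat, p = chisq_enrichment(10, 1000, 1, 1000)
        assert stat == pytest.approx(7.40438, abs=1e-4)
        assert 0 < p < 0.01

    def test_chisq_row_swap_invariant(self):
        assert chisq_enrichment(10, 1000, 1, 1000)[0] == \
            pytest.approx(chisq_enrichment(1, 1000, 10, 1000)[0])

    def test_chisq_matches_textbook_formula(self, rng):
        """Random small tables vs the direct Pearson sum to 1e-9."""
        for _ in range(50):
            r1, r2 = int(rng.integers(1, 50)), int(rng.integers(1, 50))
            m1, m2 = r1 + int(rng.integers(50, 500)), r2 + int(rng.integers(50, 500))
            obs = np.array([[r1, m1 - r1], [r2, m2 - r2]], float)
            exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
            expected = ((obs - exp) ** 2 / exp).sum()
            assert chisq_enrichment(r1, m1, r2, m2)[0] == \
                pytest.approx(expected, abs=1e-9)

    def test_count_exceeding_denominator_rejected(self):
        with pytest.raises(ValueError):
            chisq_enrichment(10, 5, 1, 100)


class TestCoverage:
    def test_strain_coverage_arithmetic(self):
        c160 = coverage_estimate(43.7e6, 100, 2, 364e6)
        c9 = coverage_estimate(37.6e6, 100, 2, 364e6)
        assert round(c160) == 24
        assert round(c9) == 21

    def test_total_bases_equal_genome_gives_one(self):
        assert coverage_estimate(500, 100, 2, 100_000) == pytest.approx(1.0)

    def test_zero_genome_rejected(self):
        with pytest.raises(ValueError):
            coverage_estimate(1e6, 100, 2, 0)
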