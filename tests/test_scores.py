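"""Entropy, mutual information, SU and the corrected coevolution scores."""

import itertools
import math

import numpy as np
import pytest

from coevostab import (
    background_product_correlation,
    column_frequencies,
    histogram_entropy_correlation,
    mutual_information,
    pair_count_histogram,
    pair_statistics,
    score_mip_zpx,
    score_znmi,
    score_zres,
    shannon_entropy,
    su_matrix,
    symmetric_uncertainty,
    threshold_pairs,
)
from coevostab.profile import EntropyProfile
from coevostab.scores import PairList, ScoreMatrix

from conftest import make_alignment, random_alignment


class TestShannonEntropy:
    def test_conserved_column_zero(self):
        aln = make_alignment(["A", "A", "A"])
        assert shannon_entropy(column_frequencies(aln, 1)) == 0.0

    def test_two_letters_half_half(self):
        aln = make_alignment(["A", "A", "R", "R"])
        assert shannon_entropy(column_frequencies(aln, 1)) == pytest.approx(1.0)

    def test_uniform_twenty_letters(self):
        aln = make_alignment([aa for aa in "GALVIPRTSCMKEQDNWYFH"])
        h = shannon_entropy(column_frequencies(aln, 1))
        assert h == pytest.approx(math.log2(20))


class TestMutualInformation:
    def test_perfect_covariation_one_bit(self, toy_alignment):
        mi, n = mutual_information(toy_alignment, 1, 2)
        assert mi == pytest.approx(1.0) and n == 4

    def test_independent_columns_zero(self, toy_alignment):
        mi, _ = mutual_information(toy_alignment, 1, 4)
        assert mi == pytest.approx(0.0, abs=1e-12)

    def test_triple_entropy_identity_on_random_pair(self):
        aln = random_alignment(30, 2, seed=21)
        mi, n = mutual_information(aln, 1, 2)
        # oracle: H(X)+H(Y)-H(X,Y) by explicit counting
        from collections import Counter

        xs = [r[0] for r in aln.rows]
        ys = [r[1] for r in aln.rows]

        def h(counter, n):
            return -sum((c / n) * math.log2(c / n) for c in counter.values())

        expected = (
            h(Counter(xs), n) + h(Counter(ys), n) - h(Counter(zip(xs, ys)), n)
        )
        assert mi == pytest.approx(expected, abs=1e-12)

    def test_exhaustive_enumeration_small_alphabet(self):
        # every alignment of up to 4 rows over a 3-letter alphabet (2 cols):
        # the plug-in MI must equal the entropy-sum oracle exactly
        from collections import Counter

        letters = "ARK"
        checked = 0
        for n_rows in (1, 2, 3, 4):
            for cells in itertools.product(letters, repeat=2 * n_rows):
                rows = [
                    cells[2 * k] + cells[2 * k + 1] for k in range(n_rows)
                ]
                aln = make_alignment(rows)
                mi, n = mutual_information(aln, 1, 2)
                xs = [r[0] for r in rows]
                ys = [r[1] for r in rows]

                def h(counter):
                    return -sum(
                        (c / n_rows) * math.log2(c / n_rows)
                        for c in counter.values()
                    )

                expected = h(Counter(xs)) + h(Counter(ys)) - h(Counter(zip(xs, ys)))
                assert mi == pytest.approx(expected, abs=1e-12)
                assert n == n_rows
                checked += 1
        assert checked == sum(9**r for r in (1, 2, 3, 4))

    def test_mi_bounded_by_min_marginal_entropy(self):
        aln = random_alignment(25, 6, seed=3, gap_rate=0.15)
        ps = pair_statistics(aln)
        for i in range(6):
            for j in range(i + 1, 6):
                if ps.n_pair[i, j] > 0:
                    assert -1e-12 <= ps.mi[i, j] <= min(
                        ps.h_cond[i, j], ps.h_cond[j, i]
                    ) + 1e-12


class TestSymmetricUncertainty:
    def test_perfect_gap_free_pair_is_one(self, toy_alignment):
        assert symmetric_uncertainty(toy_alignment, 1, 2) == pytest.approx(1.0)

    def test_gap_scaling_halves(self):
        # same covarying pair but half the rows gapped in column 2
        aln = make_alignment(["AL", "AL", "RK", "RK", "A-", "A-", "R-", "R-"])
        assert symmetric_uncertainty(aln, 1, 2) == pytest.approx(0.5)

    def test_conserved_column_gives_zero(self, toy_alignment):
        assert symmetric_uncertainty(toy_alignment, 3, 1) == 0.0

    def test_su_matrix_excludes_conserved(self, toy_alignment):
        sm = su_matrix(toy_alignment)
        assert sm.excluded == frozenset({3})
        assert sm.values == pytest.approx(sm.values.T)
        assert sm.values[0, 1] == pytest.approx(1.0)

    def test_su_in_unit_interval(self):
        aln = random_alignment(40, 8, seed=6, gap_rate=0.2)
        sm = su_matrix(aln)
        _, _, vals = sm.unique_pairs()
        assert (vals >= 0).all() and (vals <= 1 + 1e-12).all()


class TestBackgroundProductCorrelation:
    def test_exact_outer_product_gives_one(self):
        rng = np.random.default_rng(8)
        m = rng.uniform(0.5, 2.0, 12)
        vals = np.outer(m, m)
        np.fill_diagonal(vals, 0.0)
        sm = ScoreMatrix(values=vals, method="SU")
        assert background_product_correlation(sm) > 0.99

    def test_iid_random_matrix_near_zero(self):
        rng = np.random.default_rng(9)
        rs = []
        for _ in range(30):
            a = rng.normal(size=(50, 50))
            vals = a + a.T
            np.fill_diagonal(vals, 0.0)
            rs.append(background_product_correlation(ScoreMatrix(vals, "MI")))
        assert abs(np.mean(rs)) < 0.05


def _spiked_matrix(L=10, spike=5.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 0.05, size=(L, L))
    vals = (a + a.T) / 2
    vals[2, 7] = vals[7, 2] = spike
    np.fill_diagonal(vals, 0.0)
    return ScoreMatrix(values=vals, method="SU")


class TestCorrectedScores:
    def test_matrix_equal_to_its_apc_goes_flat(self):
        # a constant off-diagonal matrix equals its own average-product
        # correction exactly, so every corrected value is zero
        vals = np.full((15, 15), 0.7)
        np.fill_diagonal(vals, 0.0)
        sm = ScoreMatrix(values=vals, method="SU")
        z = score_mip_zpx(sm)
        _, _, zv = z.unique_pairs()
        assert np.allclose(zv, 0.0, atol=1e-12)

    def test_zscoring_contract_all_methods(self):
        aln = random_alignment(60, 50, seed=17, gap_rate=0.05)
        ps = pair_statistics(aln)
        su = su_matrix(ps)
        for sm in (score_mip_zpx(su), score_zres(su), score_znmi(ps)):
            _, _, vals = sm.unique_pairs()
            assert abs(vals.mean()) < 1e-9
            assert abs(vals.std() - 1.0) < 1e-9

    def test_planted_pair_tops_every_score(self):
        # one strongly covarying pair in an otherwise independent alignment
        rng = np.random.default_rng(31)
        n, L = 150, 20
        codes = rng.integers(0, 20, size=(n, L))
        codes[:, 12] = (codes[:, 4] + 3) % 20  # deterministic coupling
        aa = "GALVIPRTSCMKEQDNWYFH"
        aln = make_alignment(["".join(aa[c] for c in row) for row in codes])
        ps = pair_statistics(aln)
        su = su_matrix(ps)
        for sm in (score_mip_zpx(su), score_zres(su), score_znmi(ps)):
            ii, jj, vals = sm.unique_pairs()
            top = np.argmax(vals)
            assert {ii[top] + 1, jj[top] + 1} == {5, 13}, sm.method

    def test_zres_orthogonal_to_background_product(self):
        # OLS residuals are exactly uncorrelated with the regressor: the
        # ZRes values must be orthogonal to the column-mean products that
        # the raw SU matrix correlates with strongly
        aln = random_alignment(60, 30, seed=41)
        su = su_matrix(aln)
        ii, jj, su_vals = su.unique_pairs()
        full = np.zeros_like(su.values, dtype=bool)
        full[ii, jj] = full[jj, ii] = True
        means = np.where(full, su.values, 0.0).sum(axis=1) / full.sum(axis=1)
        prod = means[ii] * means[jj]
        raw_r = np.corrcoef(su_vals, prod)[0, 1]
        _, _, z_vals = score_zres(su).unique_pairs()
        res_r = np.corrcoef(z_vals, prod)[0, 1]
        assert raw_r > 0.3
        assert abs(res_r) < 1e-10


class TestThresholdPairs:
    def test_flat_matrix_empty(self):
        sm = ScoreMatrix(values=np.ones((6, 6)), method="SU")
        assert len(threshold_pairs(sm, 1.0)) == 0

    def test_single_spike_extracted_at_3sigma(self):
        sm = _spiked_matrix()
        pl = threshold_pairs(sm, 3.0)
        assert pl.position_pairs() == {(3, 8)}
        # direct mean/sigma arithmetic oracle
        _, _, vals = sm.unique_pairs()
        assert pl.pairs[0][2] > vals.mean() + 3 * vals.std()

    def test_counts_monotone_in_threshold(self):
        aln = random_alignment(40, 25, seed=23)
        sm = score_mip_zpx(su_matrix(aln))
        counts = [len(threshold_pairs(sm, k)) for k in (1, 2, 3, 4, 5)]
        assert counts == sorted(counts, reverse=True)

    def test_sorted_by_descending_score(self):
        aln = random_alignment(40, 15, seed=29)
        pl = threshold_pairs(su_matrix(aln), 1.0)
        scores = [s for _, _, s in pl.pairs]
        assert scores == sorted(scores, reverse=True)


class TestHistogram:
    def test_single_pair_increments_both_endpoints(self):
        pl = PairList(pairs=[(3, 7, 2.0)], threshold_sigma=1, matrix_method="SU")
        counts = pair_count_histogram(pl, 10)
        assert counts[2] == 1 and counts[6] == 1 and counts.sum() == 2

    def test_empty_list_zero_vector(self):
        pl = PairList(pairs=[], threshold_sigma=1, matrix_method="SU")
        assert pair_count_histogram(pl, 5).sum() == 0

    def test_matches_incidence_row_sums(self):
        rng = np.random.default_rng(13)
        L = 12
        pairs = []
        inc = np.zeros((L, L))
        for _ in range(20):
            i, j = sorted(rng.choice(L, 2, replace=False) + 1)
            if (i, j, 1.0) not in pairs:
                pairs.append((int(i), int(j), 1.0))
                inc[i - 1, j - 1] = inc[j - 1, i - 1] = 1
        pl = PairList(pairs=pairs, threshold_sigma=1, matrix_method="SU")
        assert pair_count_histogram(pl, L) == pytest.approx(inc.sum(axis=1))

    def test_total_is_twice_unique_pairs(self):
        aln = random_alignment(40, 15, seed=37)
        pl = threshold_pairs(su_matrix(aln), 1.0)
        counts = pair_count_histogram(pl, 15)
        assert counts.sum() == 2 * len(pl)


class TestHistogramEntropyCorrelation:
    def _profile(self, values):
        n = len(values)
        return EntropyProfile(
            values=np.asarray(values, float),
            positions=list(range(1, n + 1)),
            n_ungapped=np.full(n, 10),
            flags=np.zeros(n, dtype=bool),
        )

    def test_proportional_counts_give_r_one(self):
        prof = self._profile(np.linspace(0.5, 3.0, 20))
        counts = 2.0 * prof.values
        r, p = histogram_entropy_correlation(counts, prof, conserved=set())
        assert r == pytest.approx(1.0)

    def test_conserved_positions_excluded(self):
        prof = self._profile([1, 2, 3, 100.0])
        counts = np.array([1, 2, 3, 0.0])
        r, _ = histogram_entropy_correlation(counts, prof, conserved={4})
        assert r == pytest.approx(1.0)

    def test_shuffled_counts_near_zero(self):
        rng = np.random.default_rng(19)
        prof = self._profile(rng.uniform(0, 3, 100))
        rs = []
        for _ in range(100):
            counts = rng.permutation(prof.values)
            r, _ = histogram_entropy_correlation(counts, prof)
            rs.append(r)
        assert abs(np.mean(rs)) < 0.03
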