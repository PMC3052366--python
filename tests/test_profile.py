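"""Entropy profiles, smoothing, regions and outlier flagging."""

import math

import numpy as np
import pytest

from coevostab import (
    AA_ORDER,
    above_mean_regions,
    background_from_alignment,
    loess_smooth,
    profile_difference,
    relative_entropy_profile,
    sigma_outliers,
)
from coevostab.profile import BackgroundDistribution, interior_exterior_contrast

from conftest import make_alignment, random_alignment


class TestBackground:
    def test_single_letter_family(self):
        aln = make_alignment(["AA", "AA"])
        bg = background_from_alignment(aln, pseudocount_mass=0.0)
        assert bg.probs[AA_ORDER.index("A")] == 1.0

    def test_uniform_usage(self):
        aln = make_alignment([AA_ORDER])
        bg = background_from_alignment(aln, pseudocount_mass=0.0)
        assert bg.probs == pytest.approx(np.full(20, 0.05))

    def test_matches_global_tally(self):
        aln = random_alignment(20, 10, seed=2, gap_rate=0.1)
        bg = background_from_alignment(aln, pseudocount_mass=0.0)
        tally = {aa: 0 for aa in AA_ORDER}
        for row in aln.rows:
            for c in row:
                if c != "-":
                    tally[c] += 1
        total = sum(tally.values())
        expected = np.array([tally[aa] / total for aa in AA_ORDER])
        assert bg.probs == pytest.approx(expected)

    def test_pseudocount_strictly_positive(self):
        aln = make_alignment(["AA", "AA"])
        bg = background_from_alignment(aln, pseudocount_mass=1.0)
        assert (bg.probs > 0).all()


class TestRelativeEntropyProfile:
    def test_column_matching_background_is_zero(self):
        aln = make_alignment(["AR", "RA", "AR", "RA"])
        bg = background_from_alignment(aln, pseudocount_mass=0.0)
        prof = relative_entropy_profile(aln, bg, pseudocount_mass=0.0)
        assert prof.values == pytest.approx([0.0, 0.0], abs=1e-12)

    def test_conserved_column_closed_form(self):
        # fully conserved residue a at pseudocount 0 gives log2(1/pi_a)
        aln = make_alignment(["AR", "AK", "AR", "AK"])
        bg = background_from_alignment(aln, pseudocount_mass=0.0)
        prof = relative_entropy_profile(aln, bg, pseudocount_mass=0.0)
        pi_a = bg.probs[AA_ORDER.index("A")]
        assert prof.values[0] == pytest.approx(math.log2(1 / pi_a))

    def test_matches_hand_summation(self):
        aln = random_alignment(30, 10, seed=9, gap_rate=0.1)
        bg = background_from_alignment(aln, 1.0)
        prof = relative_entropy_profile(aln, bg, 1.0)
        for j in range(10):
            counts = {aa: 0.0 for aa in AA_ORDER}
            for row in aln.rows:
                if row[j] != "-":
                    counts[row[j]] += 1
            p = np.array(
                [counts[aa] + 1.0 * bg.probs[k] for k, aa in enumerate(AA_ORDER)]
            )
            p /= p.sum()
            expected = sum(
                pk * math.log2(pk / bgk) for pk, bgk in zip(p, bg.probs) if pk > 0
            )
            assert prof.values[j] == pytest.approx(expected, abs=1e-12)

    def test_kl_nonnegative_and_all_gap_flagged(self):
        aln = make_alignment(["A-", "R-", "K-", "G-"])
        bg = background_from_alignment(aln, 1.0)
        prof = relative_entropy_profile(aln, bg, 1.0)
        assert (prof.values >= 0).all()
        assert prof.flags[1] and prof.values[1] == 0.0

    def test_interior_conservation_raises_profile(self):
        # emulate a conserved interior: columns 10..19 drawn from a
        # low-entropy distribution, the rest uniform
        rng = np.random.default_rng(4)
        rows = []
        for _ in range(60):
            chars = [AA_ORDER[c] for c in rng.integers(0, 20, 30)]
            for j in range(10, 20):
                chars[j] = AA_ORDER[j % 3]  # nearly fixed interior columns
            rows.append("".join(chars))
        aln = make_alignment(rows)
        bg = background_from_alignment(aln, 1.0)
        prof = relative_entropy_profile(aln, bg, 1.0)
        from coevostab.profile import RegionSet

        inside, outside = interior_exterior_contrast(prof, RegionSet([(11, 20)]))
        assert inside > outside


class TestProfileDifference:
    def test_identical_profiles_zero(self):
        aln = random_alignment(10, 5, seed=1)
        bg = background_from_alignment(aln, 1.0)
        prof = relative_entropy_profile(aln, bg, 1.0)
        assert profile_difference(prof, prof) == pytest.approx(np.zeros(5))

    def test_elementwise_and_antisymmetric(self):
        a = random_alignment(10, 4, seed=2)
        b = random_alignment(10, 4, seed=3)
        bg = background_from_alignment(a, 1.0)
        p1 = relative_entropy_profile(a, bg, 1.0)
        p2 = relative_entropy_profile(b, bg, 1.0)
        d12 = profile_difference(p1, p2)
        assert d12 == pytest.approx(p1.values - p2.values)
        assert profile_difference(p2, p1) == pytest.approx(-d12)


class TestLoess:
    def test_constant_reproduced(self):
        out = loess_smooth(np.full(50, 3.7), span_residues=10)
        assert out == pytest.approx(np.full(50, 3.7), abs=1e-10)

    def test_linear_ramp_recovered(self):
        x = np.linspace(0, 5, 80)
        out = loess_smooth(x, span_residues=15)
        assert out[5:-5] == pytest.approx(x[5:-5], abs=1e-8)

    def test_matches_handcoded_tricube_regression(self):
        # independent textbook implementation: tricube weights over the
        # span-nearest neighbours, degree-1 weighted least squares
        rng = np.random.default_rng(0)
        n, span = 60, 20
        y = np.sin(np.linspace(0, 4 * np.pi, n)) + 0.1 * rng.standard_normal(n)
        x = np.arange(n, dtype=float)
        expected = np.empty(n)
        for k in range(n):
            d = np.abs(x - x[k])
            h = np.sort(d)[span - 1]
            w = np.clip(1 - (d / h) ** 3, 0, None) ** 3
            W = np.diag(w)
            X = np.column_stack([np.ones(n), x - x[k]])
            beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
            expected[k] = beta[0]
        out = loess_smooth(y, span_residues=span)
        assert out == pytest.approx(expected, abs=1e-6)

    def test_oversized_span_clamped(self):
        out = loess_smooth(np.arange(10.0), span_residues=50)
        assert len(out) == 10


class TestRegionsAndOutliers:
    def test_all_equal_gives_no_region(self):
        assert above_mean_regions(np.ones(5)).intervals == []

    def test_single_run(self):
        assert above_mean_regions(np.array([0, 0, 5, 5, 0])).intervals == [(3, 4)]

    def test_short_runs_discarded(self):
        assert above_mean_regions(np.array([0, 9, 0, 9, 0]), min_len=2).intervals == []

    def test_outlier_direct_computation(self):
        # with five zeros and one spike the spike's deviation is
        # sqrt(5) sigma > 2 sigma, whatever the spike height
        vals = np.array([0, 0, 0, 0, 0, 10.0])
        assert sigma_outliers(vals, 2.0) == [6]

    def test_constant_vector_no_outliers(self):
        assert sigma_outliers(np.ones(10), 2.0) == []

    def test_normal_tail_mass(self):
        # |z| > 2 happens with probability ~4.55% for standard normal draws
        rng = np.random.default_rng(123)
        fracs = []
        for _ in range(50):
            vals = rng.standard_normal(500)
            fracs.append(len(sigma_outliers(vals, 2.0)) / 500)
        assert np.mean(fracs) == pytest.approx(0.0455, abs=0.01)
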