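"""Per-column information-content profiles and profile post-processing.

A column's information content is the relative entropy (Kullback-Leibler
divergence, in bits) between its observed amino-acid distribution P_i and a
background distribution pi estimated from the whole family:

    I(P_i) = H(P_i || pi) = sum_a P_i(a) * log2(P_i(a) / pi_a)

High values flag positions whose residue usage departs strongly from the
family background — conserved or otherwise constrained positions.  The
profile here is a direct plug-in estimate with a single background-
proportional pseudocount; it is not an HMM emission profile (no Dirichlet
mixture priors, no sequence weighting), which carries the same positional
signal in a self-contained form.

Post-processing mirrors common profile presentation: locally weighted
(lowess) smoothing with a span given in residues, extraction of
above-mean regions, and k-sigma outlier flagging of difference profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .msa import Alignment, frequency_matrix


@dataclass
class BackgroundDistribution:
    """Background amino-acid probabilities pi_a in ``AA_ORDER``."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (20,):
            raise ValueError("background must have exactly 20 probabilities")
        if not np.isclose(self.probs.sum(), 1.0):
            raise ValueError("background probabilities must sum to 1")


@dataclass
class EntropyProfile:
    """Per-position relative entropy I(P_i) in bits.

    ``flags`` marks columns with no ungapped rows (value reported as 0).
    """

    values: np.ndarray
    positions: list[int]
    n_ungapped: np.ndarray
    flags: np.ndarray


@dataclass
class RegionSet:
    """Sorted, non-overlapping 1-based inclusive position intervals."""

    intervals: list[tuple[int, int]]


def background_from_alignment(
    aln: Alignment, pseudocount_mass: float = 1.0
) -> BackgroundDistribution:
    """Background distribution from global residue counts in the family.

    pi_a is proportional to the total count of amino acid ``a`` over all
    ungapped cells plus ``pseudocount_mass / 20``; strictly positive whenever
    the pseudocount mass is positive.
    """
    if pseudocount_mass < 0:
        raise ValueError("pseudocount_mass must be non-negative")
    enc = aln.encoded()
    counts = np.bincount(enc[enc != 20].ravel(), minlength=20).astype(float)
    if counts.sum() == 0:
        raise ValueError("alignment contains no residues (all gaps)")
    counts += pseudocount_mass / 20.0
    return BackgroundDistribution(probs=counts / counts.sum())


def relative_entropy_profile(
    aln: Alignment,
    bg: BackgroundDistribution,
    pseudocount_mass: float = 1.0,
) -> EntropyProfile:
    """Column-wise KL divergence from the background, in bits.

    Per column, P_i is the pseudocount-smoothed frequency
    ``(counts_a + pseudocount_mass * pi_a) / (n + pseudocount_mass)`` and the
    profile value is ``sum_a P_i(a) log2(P_i(a)/pi_a)``.  Gap rows are
    excluded from the counts; all-gap columns get value 0 and a flag.
    """
    if (bg.probs < 0).any():
        raise ValueError("background probabilities must be non-negative")
    enc = aln.encoded()
    L = aln.length
    values = np.zeros(L)
    n_ungapped = np.zeros(L, dtype=int)
    flags = np.zeros(L, dtype=bool)
    pi = bg.probs
    for j in range(L):
        col = enc[:, j]
        counts = np.bincount(col[col != 20], minlength=20).astype(float)
        n = counts.sum()
        n_ungapped[j] = int(n)
        if n == 0:
            flags[j] = True
            continue
        p = counts + pseudocount_mass * pi
        p /= p.sum()
        nz = p > 0
        if (pi[nz] == 0).any():
            raise ValueError(
                "background has zero mass on an observed residue; "
                "use a positive pseudocount_mass"
            )
        values[j] = float(np.sum(p[nz] * np.log2(p[nz] / pi[nz])))
    return EntropyProfile(
        values=values, positions=list(aln.positions), n_ungapped=n_ungapped, flags=flags
    )


def profile_difference(p1: EntropyProfile, p2: EntropyProfile) -> np.ndarray:
    """Element-wise ``p1 - p2`` (e.g. C23 minus N23 subfamily profiles)."""
    if len(p1.values) != len(p2.values):
        raise ValueError("profiles must have equal length")
    return p1.values - p2.values


def loess_smooth(values: np.ndarray, span_residues: int = 20) -> np.ndarray:
    """Lowess smoothing with a window given as a number of residues.

    Tricube-weighted degree-1 local regression, single pass (no
    robustification iterations), window fraction ``span_residues / L``.
    A span larger than the profile is clamped to the profile length.
    """
    values = np.asarray(values, dtype=float)
    if span_residues < 3:
        raise ValueError("span_residues must be >= 3")
    L = len(values)
    if L == 0:
        return values.copy()
    span = min(span_residues, L)
    x = np.arange(L, dtype=float)
    return _sm_lowess(values, x, frac=span / L, it=0, return_sorted=False)


def above_mean_regions(values: np.ndarray, min_len: int = 1) -> RegionSet:
    """Maximal runs of positions strictly above the mean of ``values``.

    Runs shorter than ``min_len`` are discarded.  Intervals are 1-based
    inclusive.
    """
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise ValueError("values must be non-empty")
    above = values > values.mean()
    intervals: list[tuple[int, int]] = []
    start = None
    for k, flag in enumerate(above):
        if flag and start is None:
            start = k
        elif not flag and start is not None:
            if k - start >= min_len:
                intervals.append((start + 1, k))
            start = None
    if start is not None and len(above) - start >= min_len:
        intervals.append((start + 1, len(above)))
    return RegionSet(intervals=intervals)


def sigma_outliers(values: np.ndarray, k: float = 2.0) -> list[int]:
    """1-based positions where ``|value - mean| > k * sd`` of the vector.

    A zero-variance vector yields no outliers.
    """
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise ValueError("values must be non-empty")
    sd = values.std()
    if sd == 0:
        return []
    dev = np.abs(values - values.mean())
    return [int(i) + 1 for i in np.nonzero(dev > k * sd)[0]]


def interior_exterior_contrast(
    profile: EntropyProfile, interior: RegionSet
) -> tuple[float, float]:
    """Mean profile value inside vs outside a region set (reporting helper)."""
    mask = np.zeros(len(profile.values), dtype=bool)
    pos = np.asarray(profile.positions)
    for a, b in interior.intervals:
        mask |= (pos >= a) & (pos <= b)
    return float(profile.values[mask].mean()), float(profile.values[~mask].mean())
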