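"""Mutational stability landscape: L x 20 ddG matrices and their coupling
to observed amino-acid usage.

The landscape is a matrix of folding free-energy changes ddG_{a,i}
(kcal/mol, positive = destabilising) for substituting each of the 20 amino
acids ``a`` at each reference position ``i``, e.g. computed externally with
a mutational-scan predictor such as FoldX.  Under the standard assumptions
of independent sequences and additive (non-epistatic) stability
contributions, the equilibrium frequency of residue ``a`` at position ``i``
in a family alignment should scale as

    f_{a,i}  ~  exp(-ddG_{a,i}),

so the per-position Pearson correlation between the stability vector
exp(-ddG_{.,i}) and the observed frequency vector f_{.,i} quantifies how
strongly usage at that position tracks stability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .msa import AA_ORDER


@dataclass
class EnergyMatrix:
    """L x 20 matrix of ddG_{a,i} in kcal/mol.

    Columns follow ``aa_order`` (default ``G A L V I P R T S C M K E Q D N
    W Y F H``); rows follow 1-based reference positions.
    """

    ddg: np.ndarray
    aa_order: str = AA_ORDER
    positions: list[int] | None = None

    def __post_init__(self) -> None:
        self.ddg = np.asarray(self.ddg, dtype=float)
        if self.ddg.ndim != 2 or self.ddg.shape[1] != 20:
            raise ValueError("ddg must be an L x 20 matrix")
        if sorted(self.aa_order) != sorted(AA_ORDER) or len(self.aa_order) != 20:
            raise ValueError("aa_order must be a permutation of the 20 amino acids")
        if not np.isfinite(self.ddg).all():
            raise ValueError("ddg entries must be finite")
        if self.positions is None:
            self.positions = list(range(1, self.ddg.shape[0] + 1))
        elif len(self.positions) != self.ddg.shape[0]:
            raise ValueError("positions must match the number of rows")

    @property
    def length(self) -> int:
        return self.ddg.shape[0]

    def row(self, position: int) -> np.ndarray:
        """ddG vector (20,) at a 1-based position label."""
        return self.ddg[self.positions.index(position)]

    def lookup(self, aa: str, position: int) -> float:
        """ddG for amino acid ``aa`` at a 1-based position."""
        return float(self.row(position)[self.aa_order.index(aa)])

    def reordered(self, aa_order: str = AA_ORDER) -> "EnergyMatrix":
        """Same matrix with columns permuted into another amino-acid order."""
        perm = [self.aa_order.index(a) for a in aa_order]
        return EnergyMatrix(self.ddg[:, perm], aa_order=aa_order, positions=list(self.positions))


@dataclass
class StabilityUsageReport:
    """Per-position correlation between exp(-ddG) and amino-acid usage.

    ``r`` and ``p`` have one entry per position (two-sided test of zero
    correlation over the n=20 amino-acid pairs); ``flagged`` marks positions
    where either vector is degenerate (undefined correlation, excluded from
    summaries).
    """

    r: np.ndarray
    p: np.ndarray
    flagged: np.ndarray
    positions: list[int]

    def valid(self) -> np.ndarray:
        return ~self.flagged


def read_energy_matrix(path, aa_order: str = AA_ORDER) -> EnergyMatrix:
    """Read a whitespace-delimited L x 20 ddG matrix (kcal/mol).

    One row per position, 20 numeric columns in ``aa_order``.
    """
    try:
        ddg = np.loadtxt(path, dtype=float, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in energy matrix {path}: {exc}") from None
    if ddg.shape[1] != 20:
        raise ValueError(f"expected 20 columns in {path}, found {ddg.shape[1]}")
    return EnergyMatrix(ddg, aa_order=aa_order)


def write_energy_matrix(em: EnergyMatrix, path) -> None:
    np.savetxt(path, em.ddg, fmt="%.6f")


def merge_conformer_matrices(
    mats: list[EnergyMatrix], weights: list[float]
) -> EnergyMatrix:
    """Element-wise weighted mean of conformer-specific ddG matrices.

    Weights are normalised internally, so the merge is invariant to weight
    rescaling (e.g. 58:24:18 population ratios can be given as counts or
    fractions).
    """
    if len(mats) != len(weights):
        raise ValueError("one weight per matrix required")
    w = np.asarray(weights, dtype=float)
    if (w < 0).any() or w.sum() == 0:
        raise ValueError("weights must be non-negative and not all zero")
    shape = mats[0].ddg.shape
    order = mats[0].aa_order
    for m in mats[1:]:
        if m.ddg.shape != shape:
            raise ValueError("matrices must share the same shape")
        if m.aa_order != order:
            raise ValueError("matrices must share the same amino-acid order")
    merged = np.tensordot(w / w.sum(), np.stack([m.ddg for m in mats]), axes=1)
    return EnergyMatrix(merged, aa_order=order, positions=list(mats[0].positions))


def stability_vector(em: EnergyMatrix, position: int) -> np.ndarray:
    """exp(-ddG_{a,i}) over the 20 amino acids at one position."""
    return np.exp(-em.row(position))


def stability_usage_correlation(
    em: EnergyMatrix, freqs: np.ndarray
) -> StabilityUsageReport:
    """Per-position Pearson correlation of exp(-ddG) with observed usage.

    Parameters
    ----------
    em
        The stability landscape.
    freqs
        L x 20 observed frequency matrix aligned to ``em.aa_order``
        (raw frequencies, no pseudocount); NaN rows (all-gap columns) are
        flagged.

    Returns a report with two-sided p-values from the exact t-test of zero
    correlation at n = 20.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != em.ddg.shape:
        raise ValueError("frequency matrix shape must match the energy matrix")
    L = em.length
    r = np.full(L, np.nan)
    p = np.full(L, np.nan)
    flagged = np.zeros(L, dtype=bool)
    stab = np.exp(-em.ddg)
    for k in range(L):
        f = freqs[k]
        s = stab[k]
        if np.isnan(f).any() or f.std() == 0 or s.std() == 0:
            flagged[k] = True
            continue
        res = stats.pearsonr(s, f)
        r[k], p[k] = res.statistic, res.pvalue
    return StabilityUsageReport(r=r, p=p, flagged=flagged, positions=list(em.positions))


def subfamily_correlation_difference(
    rep_a: StabilityUsageReport, rep_b: StabilityUsageReport, k_sigma: float = 2.0
) -> tuple[np.ndarray, list[int]]:
    """Difference of two per-position correlation vectors and its outliers.

    Returns the element-wise ``r_a - r_b`` and the 1-based positions whose
    difference deviates from the mean by more than ``k_sigma`` standard
    deviations (positions flagged in either report are set to NaN and
    excluded from the outlier statistics).
    """
    if len(rep_a.r) != len(rep_b.r):
        raise ValueError("reports must have equal length")
    diff = rep_a.r - rep_b.r
    valid = rep_a.valid() & rep_b.valid()
    diff = np.where(valid, diff, np.nan)
    finite = diff[valid]
    if len(finite) == 0 or finite.std() == 0:
        return diff, []
    dev = np.abs(diff - finite.mean())
    idx = np.nonzero(valid & (dev > k_sigma * finite.std()))[0]
    return diff, [rep_a.positions[i] for i in idx]
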