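"""Coupling of coevolution scores to the stability landscape.

For a coevolving pair of positions (i, j), each sequence in the alignment
contributes the two stability terms ddG_i and ddG_j of its actual residues
at those positions (looked up in the L x 20 landscape).  Averaged over the
sequences of the alignment, two magnitudes characterise the pair:

    ddg_sum     = < ddG_i + ddG_j >        (additive joint contribution)
    ddg_absdiff = < |ddG_i - ddG_j| >      (similar vs opposite effects)

A pair with ddg_absdiff > ddg_sum exerts, on average, opposite effects on
stability at its two positions — the signature expected from cycles of a
destabilising mutation followed by a compensating suppressor.  Pairs where
both magnitudes are small are better explained by successions of (nearly)
neutral covarions.  Across all pairs above a score threshold, the Pearson
correlation of score with each magnitude (one-sided, negative alternative)
tests whether strong coevolution avoids destabilising combinations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .energy import EnergyMatrix
from .msa import GAP_CODE, Alignment
from .scores import PairList


@dataclass
class PairStabilityRecord:
    """Score and sequence-averaged stability magnitudes of one pair."""

    i: int
    j: int
    score: float
    ddg_sum: float
    ddg_absdiff: float
    n_seqs: int

    @property
    def opposite(self) -> bool:
        """True when |ddG_i - ddG_j| exceeds ddG_i + ddG_j on average."""
        return self.ddg_absdiff > self.ddg_sum


@dataclass
class CorrelationSummary:
    """Score-vs-stability correlations over the pairs at one threshold.

    One-sided p-values test zero correlation against the negative
    alternative.  ``flagged`` marks a degenerate summary (constant score or
    magnitude vectors).
    """

    method: str
    k_sigma: float
    n_pairs: int
    r_sum: float
    p_sum: float
    r_absdiff: float
    p_absdiff: float
    frac_opposite: float
    flagged: bool = False


def sequence_pair_ddg(
    row: str, em: EnergyMatrix, i: int, j: int
) -> tuple[float, float] | None:
    """The (ddG_i, ddG_j) contributed by one aligned sequence, or None.

    Looks up the row's residues at 1-based reference positions i and j in
    the energy matrix; a row gapped at either position contributes nothing.
    """
    ci = em.positions.index(i)
    cj = em.positions.index(j)
    ai, aj = row[ci], row[cj]
    if ai == "-" or aj == "-":
        return None
    return em.lookup(ai, i), em.lookup(aj, j)


def pair_magnitudes(
    aln: Alignment, em: EnergyMatrix, i: int, j: int
) -> tuple[float, float, int]:
    """Sequence-averaged (ddg_sum, ddg_absdiff, n_seqs) for positions i, j.

    Rows gapped at either position are excluded from both averages; with no
    contributing row the magnitudes are NaN.
    """
    if i == j:
        raise ValueError("i and j must differ")
    enc = aln.encoded()
    pos_index = {p: k for k, p in enumerate(aln.positions)}
    xi = enc[:, pos_index[i]]
    xj = enc[:, pos_index[j]]
    shared = (xi != GAP_CODE) & (xj != GAP_CODE)
    n = int(shared.sum())
    if n == 0:
        return float("nan"), float("nan"), 0
    ddg_i = em.row(i)[xi[shared]]
    ddg_j = em.row(j)[xj[shared]]
    return (
        float((ddg_i + ddg_j).mean()),
        float(np.abs(ddg_i - ddg_j).mean()),
        n,
    )


def pair_stability_records(
    aln: Alignment, em: EnergyMatrix, pl: PairList
) -> list[PairStabilityRecord]:
    """Stability magnitudes for every pair of a threshold pair list."""
    records = []
    for i, j, score in pl.pairs:
        s, d, n = pair_magnitudes(aln, em, i, j)
        records.append(
            PairStabilityRecord(i=i, j=j, score=score, ddg_sum=s, ddg_absdiff=d, n_seqs=n)
        )
    return records


def score_stability_correlation(
    records: list[PairStabilityRecord], k_sigma: float, method: str = ""
) -> CorrelationSummary:
    """Correlate pair scores with their stability magnitudes.

    Pearson r of score vs ddg_sum and vs ddg_absdiff over the records, with
    one-sided p-values against the negative alternative, plus the fraction
    of pairs with opposite effects.
    """
    recs = [r for r in records if r.n_seqs > 0]
    if len(recs) < 3:
        raise ValueError("need at least 3 records")
    score = np.array([r.score for r in recs])
    dsum = np.array([r.ddg_sum for r in recs])
    dabs = np.array([r.ddg_absdiff for r in recs])
    frac = float(np.mean([r.opposite for r in recs]))
    if score.std() == 0 or dsum.std() == 0 or dabs.std() == 0:
        return CorrelationSummary(
            method=method, k_sigma=k_sigma, n_pairs=len(recs),
            r_sum=float("nan"), p_sum=float("nan"),
            r_absdiff=float("nan"), p_absdiff=float("nan"),
            frac_opposite=frac, flagged=True,
        )
    rs = stats.pearsonr(score, dsum, alternative="less")
    ra = stats.pearsonr(score, dabs, alternative="less")
    return CorrelationSummary(
        method=method, k_sigma=k_sigma, n_pairs=len(recs),
        r_sum=float(rs.statistic), p_sum=float(rs.pvalue),
        r_absdiff=float(ra.statistic), p_absdiff=float(ra.pvalue),
        frac_opposite=frac,
    )


def classify_mechanism(records: list[PairStabilityRecord]) -> list[str]:
    """Label each pair 'suppression-like' or 'covarion-like'.

    Suppression-like iff the opposite-effects flag is set (strict
    inequality; ties count as covarion-like).  The labels are reporting
    conveniences describing the average stability signature, not mechanistic
    inferences about individual pairs.
    """
    return ["suppression-like" if r.opposite else "covarion-like" for r in records]
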