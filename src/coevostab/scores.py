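"""Coevolution scoring of alignment column pairs.

The raw signal is mutual information (MI) between two alignment columns,
estimated by plug-in from the joint residue frequencies.  Gap handling
follows the pairwise-complete rule: a row gapped in either column of a pair
is dropped for that pair, and the marginals are recomputed on the shared
rows.  Symmetric uncertainty SU = 2*MI/(H_i + H_j) normalises MI into
[0, 1]; to down-weight sparsely populated pairs the SU value is then scaled
linearly by the fraction of mutually ungapped rows, n_pair / n_rows.

Raw MI/SU matrices carry a strong multiplicative background: the score of a
pair is well predicted by the product of the mean scores of its two columns
(positional entropy plus phylogenetic bias).  Three corrected scores remove
this background trend and z-standardise the result:

``Zpx``
    Average-product correction (APC = mean_i * mean_j / grand mean)
    subtracted from each pair, the residual z-scored within each of the two
    columns, the two column z-scores averaged, and the combined matrix
    z-scored globally.
``ZRes``
    Least-squares regression of the pair scores on the column-mean
    products; the residuals z-scored globally.
``ZNMI``
    Joint-entropy-normalised MI (NMI = MI / H(X,Y)); each pair z-scored
    against a null mean/variance built from pair-count-weighted column-wise
    NMI distributions, then standardised globally.

All three obey the z-scoring contract: mean 0 and standard deviation 1
over scored unique pairs.  Coevolving pairs are extracted at k-sigma
thresholds over the scored unique pairs of a matrix, with columns that are
fully conserved or all-gap excluded from every statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .msa import GAP_CODE, Alignment, ColumnFrequencies
from .profile import EntropyProfile

_LOG2 = np.log(2.0)


def _entropy_from_counts(counts: np.ndarray) -> float:
    """Shannon entropy in bits from a count vector (0 log 0 = 0)."""
    n = counts.sum()
    if n == 0:
        raise ValueError("empty distribution")
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def shannon_entropy(col: ColumnFrequencies) -> float:
    """Shannon entropy (bits) of one column's residue distribution."""
    if col.n_ungapped == 0:
        raise ValueError("entropy undefined for an all-gap column")
    return _entropy_from_counts(col.counts.astype(float))


@dataclass
class PairStatistics:
    """All pairwise column statistics of an alignment, computed in one pass.

    Symmetric L x L arrays: ``mi`` (bits), ``h_joint`` (bits), ``n_pair``
    (mutually ungapped rows); ``h_cond[i, j]`` is the entropy of column i
    restricted to the rows shared with j.  ``h_col`` is the plain per-column
    entropy and ``excluded`` the 1-based labels of columns that are fully
    conserved or all-gap.
    """

    mi: np.ndarray
    h_joint: np.ndarray
    h_cond: np.ndarray
    n_pair: np.ndarray
    h_col: np.ndarray
    n_rows: int
    excluded: frozenset[int]
    positions: list[int]

    @property
    def length(self) -> int:
        return self.mi.shape[0]

    def excluded_indices(self) -> np.ndarray:
        pos = {p: k for k, p in enumerate(self.positions)}
        return np.array(sorted(pos[p] for p in self.excluded), dtype=int)


@dataclass
class ScoreMatrix:
    """Symmetric L x L coevolution score matrix.

    ``method`` is one of MI, SU, MIp, Zpx, ZRes, ZNMI.  The diagonal is not
    meaningful and is ignored by all consumers.  ``excluded`` holds 1-based
    position labels of fully conserved / all-gap columns, which are omitted
    from all pair statistics.
    """

    values: np.ndarray
    method: str
    excluded: frozenset[int] = field(default_factory=frozenset)
    pair_n: np.ndarray | None = None
    positions: list[int] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("score matrix must be square")
        if self.positions is None:
            self.positions = list(range(1, self.values.shape[0] + 1))

    @property
    def length(self) -> int:
        return self.values.shape[0]

    def _scored_mask(self) -> np.ndarray:
        """Boolean upper-triangle mask of scored unique pairs."""
        L = self.length
        mask = np.triu(np.ones((L, L), dtype=bool), k=1)
        if self.excluded:
            pos = {p: k for k, p in enumerate(self.positions)}
            idx = [pos[p] for p in self.excluded]
            mask[idx, :] = False
            mask[:, idx] = False
        return mask

    def unique_pairs(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(i_idx, j_idx, values) over scored unique pairs, 0-based indices."""
        ii, jj = np.nonzero(self._scored_mask())
        return ii, jj, self.values[ii, jj]


@dataclass
class PairList:
    """Coevolving pairs above a k-sigma score threshold, sorted by score.

    ``pairs`` holds (i, j, score) with 1-based position labels and i < j.
    """

    pairs: list[tuple[int, int, float]]
    threshold_sigma: float
    matrix_method: str

    def __len__(self) -> int:
        return len(self.pairs)

    def position_pairs(self) -> set[tuple[int, int]]:
        return {(i, j) for i, j, _ in self.pairs}


def pair_statistics(aln: Alignment) -> PairStatistics:
    """Compute MI, joint entropies and pair counts for all column pairs.

    Rows gapped in either column of a pair are excluded for that pair and
    the marginal entropies are recomputed on the shared rows (``h_cond``).
    """
    enc = aln.encoded().astype(np.int64)
    n, L = enc.shape
    mi = np.zeros((L, L))
    h_joint = np.zeros((L, L))
    h_cond = np.zeros((L, L))
    n_pair = np.zeros((L, L), dtype=np.int64)
    h_col = np.zeros(L)
    excluded: set[int] = set()
    ungapped = enc != GAP_CODE
    for j in range(L):
        col = enc[ungapped[:, j], j]
        if len(col) == 0:
            excluded.add(aln.positions[j])
            continue
        counts = np.bincount(col, minlength=20)
        h_col[j] = _entropy_from_counts(counts.astype(float))
        if (counts > 0).sum() <= 1:
            excluded.add(aln.positions[j])
    for i in range(L):
        joint_code_base = enc[:, i] * 21
        for j in range(i + 1, L):
            shared = ungapped[:, i] & ungapped[:, j]
            m = int(shared.sum())
            n_pair[i, j] = n_pair[j, i] = m
            if m == 0:
                continue
            codes = joint_code_base[shared] + enc[shared, j]
            joint = np.bincount(codes, minlength=441)
            joint = joint[joint > 0].astype(float)
            hj = _entropy_from_counts(joint)
            ci = np.bincount(enc[shared, i], minlength=20).astype(float)
            cj = np.bincount(enc[shared, j], minlength=20).astype(float)
            hi = _entropy_from_counts(ci)
            hjj = _entropy_from_counts(cj)
            h_joint[i, j] = h_joint[j, i] = hj
            h_cond[i, j] = hi
            h_cond[j, i] = hjj
            mi[i, j] = mi[j, i] = max(hi + hjj - hj, 0.0)
    return PairStatistics(
        mi=mi,
        h_joint=h_joint,
        h_cond=h_cond,
        n_pair=n_pair,
        h_col=h_col,
        n_rows=n,
        excluded=frozenset(excluded),
        positions=list(aln.positions),
    )


def mutual_information(aln: Alignment, i: int, j: int) -> tuple[float, int]:
    """Plug-in MI (bits) between columns at 1-based positions i and j.

    Returns ``(mi, n_pair)``; rows gapped at either position are excluded
    and the marginals are recomputed on the shared rows.  With no shared
    ungapped row the MI is undefined and NaN is returned.
    """
    if i == j:
        raise ValueError("i and j must differ")
    xi = aln.column(i).astype(np.int64)
    xj = aln.column(j).astype(np.int64)
    shared = (xi != GAP_CODE) & (xj != GAP_CODE)
    m = int(shared.sum())
    if m == 0:
        return float("nan"), 0
    joint = np.bincount(xi[shared] * 21 + xj[shared], minlength=441).astype(float)
    hi = _entropy_from_counts(np.bincount(xi[shared], minlength=20).astype(float))
    hj = _entropy_from_counts(np.bincount(xj[shared], minlength=20).astype(float))
    hij = _entropy_from_counts(joint[joint > 0])
    return max(hi + hj - hij, 0.0), m


def symmetric_uncertainty(aln: Alignment, i: int, j: int) -> float:
    """Gap-scaled symmetric uncertainty of columns i and j.

    ``SU = 2 MI / (H_i + H_j)`` on mutually ungapped rows, multiplied by
    ``n_pair / n_rows``; defined as 0 when ``H_i + H_j = 0``.
    """
    mi, m = mutual_information(aln, i, j)
    if m == 0:
        return float("nan")
    xi = aln.column(i).astype(np.int64)
    xj = aln.column(j).astype(np.int64)
    shared = (xi != GAP_CODE) & (xj != GAP_CODE)
    hi = _entropy_from_counts(np.bincount(xi[shared], minlength=20).astype(float))
    hj = _entropy_from_counts(np.bincount(xj[shared], minlength=20).astype(float))
    if hi + hj == 0:
        return 0.0
    return 2.0 * mi / (hi + hj) * (m / aln.n_seqs)


def su_matrix(source: Alignment | PairStatistics) -> ScoreMatrix:
    """Matrix of gap-scaled symmetric uncertainties for all column pairs.

    Fully conserved and all-gap columns are recorded in ``excluded`` and
    omitted from downstream pair statistics.
    """
    ps = source if isinstance(source, PairStatistics) else pair_statistics(source)
    hsum = ps.h_cond + ps.h_cond.T
    with np.errstate(invalid="ignore", divide="ignore"):
        su = np.where(hsum > 0, 2.0 * ps.mi / np.where(hsum > 0, hsum, 1.0), 0.0)
    su *= ps.n_pair / ps.n_rows
    np.fill_diagonal(su, 0.0)
    return ScoreMatrix(
        values=su,
        method="SU",
        excluded=ps.excluded,
        pair_n=ps.n_pair,
        positions=list(ps.positions),
    )


def _column_means(sm: ScoreMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-column mean score over scored partners, and the scored-pair mask."""
    mask = sm._scored_mask()
    full = mask | mask.T
    with np.errstate(invalid="ignore"):
        sums = np.where(full, sm.values, 0.0).sum(axis=1)
        counts = full.sum(axis=1)
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return means, mask


def background_product_correlation(sm: ScoreMatrix) -> float:
    """Pearson r between pair scores and column-mean products.

    Quantifies the multiplicative background: how well score(i, j) is
    predicted by mean_i * mean_j over scored unique pairs.
    """
    means, mask = _column_means(sm)
    ii, jj = np.nonzero(mask)
    if len(ii) < 3:
        raise ValueError("need at least 3 scored unique pairs")
    prod = means[ii] * means[jj]
    vals = sm.values[ii, jj]
    if prod.std() == 0 or vals.std() == 0:
        return float("nan")
    return float(stats.pearsonr(vals, prod).statistic)


def _global_zscore(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Z-score a symmetric matrix over its scored unique pairs (population sd)."""
    sel = values[mask]
    mu, sd = sel.mean(), sel.std()
    if sd == 0:
        out = np.zeros_like(values)
    else:
        out = (values - mu) / sd
    full = mask | mask.T
    out = np.where(full, out, 0.0)
    np.fill_diagonal(out, 0.0)
    return out


def score_mip_zpx(sm: ScoreMatrix) -> ScoreMatrix:
    """APC-corrected, column- then globally-z-scored coevolution score (Zpx).

    The average-product correction ``APC = mean_i * mean_j / grand_mean``
    is subtracted from each scored pair; the residual (MIp) is z-scored
    within column i and within column j, the two z-scores averaged, and the
    combined matrix standardised globally over scored unique pairs.
    """
    means, mask = _column_means(sm)
    ii, jj = np.nonzero(mask)
    grand = sm.values[ii, jj].mean()
    if grand == 0:
        raise ValueError("grand mean of scores is zero; APC undefined")
    full = mask | mask.T
    apc = np.outer(means, means) / grand
    mip = np.where(full, sm.values - apc, 0.0)
    # per-column z of MIp over scored partners
    counts = full.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        col_mu = np.where(full, mip, 0.0).sum(axis=1) / np.maximum(counts, 1)
        col_var = (
            np.where(full, (mip - col_mu[:, None]) ** 2, 0.0).sum(axis=1)
            / np.maximum(counts, 1)
        )
    col_sd = np.sqrt(col_var)
    safe_sd = np.where(col_sd > 0, col_sd, 1.0)
    z_rows = (mip - col_mu[:, None]) / safe_sd[:, None]
    z_rows = np.where(col_sd[:, None] > 0, z_rows, 0.0)
    combined = 0.5 * (z_rows + z_rows.T)
    return ScoreMatrix(
        values=_global_zscore(combined, mask),
        method="Zpx",
        excluded=sm.excluded,
        pair_n=sm.pair_n,
        positions=list(sm.positions),
    )


def score_zres(sm: ScoreMatrix) -> ScoreMatrix:
    """Globally z-scored residuals of scores regressed on the background.

    Ordinary least-squares fit (with intercept) of the scored unique-pair
    values on the column-mean products; the residuals, z-scored globally,
    form the ZRes matrix.
    """
    means, mask = _column_means(sm)
    ii, jj = np.nonzero(mask)
    prod = means[ii] * means[jj]
    vals = sm.values[ii, jj]
    if prod.std() == 0:
        raise ValueError("degenerate background regressor")
    slope, intercept = np.polyfit(prod, vals, 1)
    L = sm.length
    resid = np.zeros((L, L))
    r = vals - (slope * prod + intercept)
    resid[ii, jj] = r
    resid[jj, ii] = r
    return ScoreMatrix(
        values=_global_zscore(resid, mask),
        method="ZRes",
        excluded=sm.excluded,
        pair_n=sm.pair_n,
        positions=list(sm.positions),
    )


def score_znmi(source: Alignment | PairStatistics) -> ScoreMatrix:
    """Z-scored joint-entropy-normalised MI (ZNMI).

    NMI(i, j) = MI / H(X, Y) on mutually ungapped rows (0 when the joint
    entropy vanishes).  For each pair a null expectation and variance are
    built from the pair-count-weighted mean and variance of NMI within each
    of the two columns (pooled as their average); the pair is z-scored
    against this null and the matrix standardised globally.
    """
    ps = source if isinstance(source, PairStatistics) else pair_statistics(source)
    L = ps.length
    with np.errstate(invalid="ignore", divide="ignore"):
        nmi = np.where(ps.h_joint > 0, ps.mi / np.where(ps.h_joint > 0, ps.h_joint, 1.0), 0.0)
    np.fill_diagonal(nmi, 0.0)
    base = ScoreMatrix(
        values=nmi, method="NMI", excluded=ps.excluded,
        pair_n=ps.n_pair, positions=list(ps.positions),
    )
    mask = base._scored_mask()
    full = mask | mask.T
    w = np.where(full, ps.n_pair, 0).astype(float)
    wsum = w.sum(axis=1)
    safe = np.maximum(wsum, 1.0)
    col_mu = (w * nmi).sum(axis=1) / safe
    col_var = (w * (nmi - col_mu[:, None]) ** 2).sum(axis=1) / safe
    exp_pair = 0.5 * (col_mu[:, None] + col_mu[None, :])
    var_pair = 0.5 * (col_var[:, None] + col_var[None, :])
    sd_pair = np.sqrt(var_pair)
    z = np.where(sd_pair > 0, (nmi - exp_pair) / np.where(sd_pair > 0, sd_pair, 1.0), 0.0)
    return ScoreMatrix(
        values=_global_zscore(z, mask),
        method="ZNMI",
        excluded=ps.excluded,
        pair_n=ps.n_pair,
        positions=list(ps.positions),
    )


def threshold_pairs(sm: ScoreMatrix, k_sigma: float) -> PairList:
    """Unique pairs scoring strictly above mean + k*sigma of the matrix.

    Mean and sigma are computed over scored unique off-diagonal pairs
    (excluded columns omitted); ties at exactly the threshold are not
    included.  Pairs are returned sorted by descending score.
    """
    if k_sigma <= 0:
        raise ValueError("k_sigma must be positive")
    ii, jj, vals = sm.unique_pairs()
    if len(vals) < 2:
        raise ValueError("need at least 2 scored unique pairs")
    cut = vals.mean() + k_sigma * vals.std()
    keep = vals > cut
    order = np.argsort(-vals[keep], kind="stable")
    pos = sm.positions
    pairs = [
        (pos[int(a)], pos[int(b)], float(v))
        for a, b, v in zip(ii[keep][order], jj[keep][order], vals[keep][order])
    ]
    return PairList(pairs=pairs, threshold_sigma=k_sigma, matrix_method=sm.method)


def pair_count_histogram(pl: PairList, L: int, positions: list[int] | None = None) -> np.ndarray:
    """Number of threshold pairs containing each position.

    Each pair increments both endpoints, so the histogram total is twice
    the unique-pair count.
    """
    positions = positions or list(range(1, L + 1))
    index = {p: k for k, p in enumerate(positions)}
    counts = np.zeros(L, dtype=np.int64)
    for i, j, _ in pl.pairs:
        counts[index[i]] += 1
        counts[index[j]] += 1
    return counts


def histogram_entropy_correlation(
    counts: np.ndarray,
    profile: EntropyProfile,
    conserved: set[int] | frozenset[int] = frozenset(),
) -> tuple[float, float]:
    """Pearson r (and two-sided p) of pair counts vs the entropy profile.

    Positions in ``conserved`` (fully conserved columns, which can take
    part in no coevolving pair) are excluded from the correlation.
    """
    counts = np.asarray(counts, dtype=float)
    if len(counts) != len(profile.values):
        raise ValueError("counts and profile must have equal length")
    keep = np.array([p not in conserved for p in profile.positions])
    x, y = counts[keep], profile.values[keep]
    if len(x) < 3 or x.std() == 0 or y.std() == 0:
        return float("nan"), float("nan")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
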