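# Methods

## The model

The package treats a protein family as an aligned sample of sequences over
the 20 canonical amino acids plus a gap symbol, and a structure as an L×20
matrix of folding free-energy changes ΔΔG_{a,i} (kcal/mol, positive =
destabilising) for placing amino acid *a* at reference position *i*. Two
assumptions connect them:

1. **Independence + additivity.** Sequences are treated as independent
   draws and per-position stability contributions as additive (no explicit
   epistasis). Under these assumptions the equilibrium usage of residue *a*
   at position *i* should scale as f_{a,i} ∝ exp(−ΔΔG_{a,i}), so the
   Pearson correlation between the stability vector exp(−ΔΔG_{·,i}) and
   the observed frequency vector f_{·,i} (n = 20 points per position)
   measures how strongly usage tracks stability. The exponential form is
   used directly (β = 1, no RT scaling): correlations are invariant to
   positive rescaling of ΔΔG only up to the curvature of the exponential,
   so this choice does affect r values and is fixed package-wide.
2. **Covariation as statistical dependence.** Coevolution between columns
   is measured by plug-in mutual information and derived scores; no
   phylogenetic tree is modelled. Shared ancestry therefore appears as a
   bias (see *Background correction*), not as an explicit term.

## Gap conventions

Gaps are never part of the alphabet. Column statistics exclude gap rows;
pair statistics follow the pairwise-complete rule (a row gapped in either
column is dropped for that pair, with marginal entropies recomputed on the
shared rows); SU is additionally scaled by n_pair/n_rows, which linearly
down-weights sparsely populated pairs. Ambiguous residues (`X`) are
normalised to gaps on input so the 20-letter alphabet of the energy matrix
stays exact. The same exclusion rule is applied to the per-pair stability
averages ⟨ΔΔG_i+ΔΔG_j⟩ and ⟨|ΔΔG_i−ΔΔG_j|⟩, mirroring the MI convention.

## Profiles

The information content of a column is the KL divergence (bits) of its
pseudocount-smoothed distribution from a background π estimated from the
family's global residue counts. The smoothing adds `pseudocount_mass · π_a`
to the counts (default mass 1.0 — one total pseudo-observation, enough to
keep profiles finite in small subfamilies without drowning the signal).
This is a deliberate simplification of profile-HMM machinery: no Dirichlet
mixture priors and no sequence weighting, which preserves the positional
signal in monotone-equivalent form but will not reproduce HMM emission
scores numerically. Smoothing uses statsmodels' lowess (tricube weights,
degree-1 local regression, single pass) with the window given as a span in
residues (default 20) converted to the fraction span/L; an oversized span
is clamped to L.

## Coevolution scores and background correction

Raw MI/SU matrices are dominated by a multiplicative background: the score
of pair (i,j) is well predicted by the product of the column mean scores
m_i·m_j (positional entropy plus shared-ancestry bias; the finite-sample
MI bias itself factorises approximately over columns, which is why the
background is product-shaped). `background_product_correlation` reports the
Pearson r between pair scores and these products. Three corrections remove
the trend; all operate on the gap-scaled SU matrix by default (the matrix
built first in the analysis) and end with a global z-scoring over scored
unique pairs, so each corrected matrix has pair mean 0 and sd 1 by
construction:

- **Zpx** — subtract the average-product correction APC = m_i·m_j/mean,
  z-score the residual within each of its two columns, average the two
  column z-scores, z-score globally. The column-combination rule
  (arithmetic mean) is isolated in one function for substitution.
- **ZRes** — ordinary least squares (with intercept) of pair scores on the
  column-mean products; residuals z-scored globally. Residuals are exactly
  orthogonal to the background regressor.
- **ZNMI** — normalise MI by the joint entropy (NMI = MI/H(X,Y), 0 when the
  joint entropy vanishes), then z-score each pair against a null whose mean
  and variance are the pair-count-weighted mean and variance of NMI within
  each of the two columns, pooled as their average; standardise globally.
  The null construction reconstructs a product-based expectation at the
  level of detail available and is likewise isolated for substitution.

Columns that are fully conserved (a single residue after gap exclusion) or
all-gap are excluded from every pair statistic — they can take part in no
coevolving pair and would deflate the threshold σ. Threshold extraction
keeps unique pairs with score strictly above mean + k·σ of the scored
unique pairs (ties excluded); the per-position histogram increments both
endpoints of each pair, so its total is twice the unique-pair count.
Population (ddof = 0) standard deviations are used throughout scoring.

## Redundancy filtering

Pairwise identity is matches over mutually ungapped columns (0 when no
column is shared). Redundancy reduction is a greedy single pass in input
order, keeping a row iff its identity to every previously kept row is ≤ the
ceiling — deterministic and order-stable, with no external clustering tool.
Different reduction algorithms would keep slightly different sequence sets
at the same ceiling.

## Stability coupling of pairs

For each pair above threshold, ⟨ΔΔG_i+ΔΔG_j⟩ and ⟨|ΔΔG_i−ΔΔG_j|⟩ average
the looked-up contributions of each sequence's actual residues. Score vs
magnitude correlations use one-sided p-values against the negative
alternative (the hypothesis of interest is that strong coevolution avoids
destabilising combinations); all other tests in the package are two-sided.
A pair is labelled *suppression-like* iff ⟨|ΔΔG_i−ΔΔG_j|⟩ strictly exceeds
⟨ΔΔG_i+ΔΔG_j⟩ (ties are covarion-like); the labels are reporting
conveniences over the average signature, not per-pair mechanistic claims.

## The synthetic generator

Each column's sampling distribution is a random Dirichlet preference
(α = 0.5, sparse enough to give realistic residue repertoires) multiplied
by exp(−β·ΔΔG) and, when a conservation profile is given, tempered —
raised to a power 1/t found by bisection — until its entropy matches the
per-column target (met to ≪ 0.05 bits; the bisection runs on log t, which
is monotone in entropy). A planted pair (i, j, c) draws the residue at j
as a deterministic rank-matching permutation of the residue at i with
probability c, independently otherwise: c = 0 gives MI 0, c = 1 gives
MI = min(H_i, H_j) exactly. Lineage duplication copies each founder with
i.i.d. per-cell remutation; gaps are injected i.i.d.; subfamily labels
split the rows by a fraction. All randomness flows from the spec seed
through named child streams.

What the generator does *not* emulate: tree-structured descent (duplication
is a one-level star phylogeny), correlated gap blocks (indels are i.i.d.),
selection acting jointly on pairs (the joint distribution of a planted pair
is a coupling mixture, not a Boltzmann pair potential), and any structural
contact geometry. Passing tests therefore demonstrate correctness of the
statistics and recoverability of planted signal under realistic marginals —
not performance on real families with deep phylogenetic structure.

Benchmark conditions are frozen as constructors:

- `planted_benchmark_spec` — 200 gap-free sequences, 100 columns with
  entropy targets uniform in [1.5, 3] bits, five disjoint pairs at
  coupling 0.9. Sized so that the planted MI (≳ 1 bit) clears the
  finite-sample background at n = 200 without being trivial.
- `usage_coupling_spec` — 300 sequences, 100 columns, free entropies, no
  planted pairs; the Dirichlet preference breaks the scale degeneracy of
  the Boltzmann factor so the usage imprint grows cleanly with β.
- `stability_trend_benchmark` — 40 pairs with couplings spread over
  [0.25, 0.95], stronger couplings assigned to positions with the mildest
  expected ΔΔG under Boltzmann usage, all columns tempered to 2.5 bits so
  coupling (not conservation) drives the scores. This emulates selection
  retaining strong covariation preferentially where its stability cost is
  low; the negative score-vs-⟨ΔΔG_i+ΔΔG_j⟩ correlation and its growth
  with the σ threshold then emerge through the full pipeline. The growth
  is assessed as the sign of the least-squares slope of |r| against σ:
  at the highest thresholds only the planted pairs remain, so |r| plateaus
  rather than increasing strictly step by step.

A known empirical subtlety: lineage duplication inflates the *level* of the
MI background (the shrunken effective sample roughly doubles mean pair MI
in the tested conditions) while slightly *reducing* the product-structure
correlation, because duplication drives the matrix toward the founder-only
statistics whose pair-specific noise is larger. The redundancy sweep
(`sweep_redundancy`) exists to make this dependence visible on real data.

## Numerical choices and degenerate inputs

Logs are base 2 (bits) everywhere; 0·log 0 ≡ 0. MI is clipped at 0 against
rounding. Degenerate cases are flagged rather than silently dropped:
all-gap columns (profile value 0 + flag, NaN frequencies), zero-variance
vectors in correlations (flagged positions / flagged summaries, excluded
from aggregates), a constant score matrix (no threshold pairs), zero
column-z denominators in Zpx (z set to 0). Pipeline outputs are a pure
function of (inputs, config, seed); numeric tables are byte-identical
across reruns, and the manifest records a SHA-256 config hash.

## Problem sizes

The validation suite runs the planted-recovery benchmark over 50 seeds,
the β-recovery study over 20 seeds × 3 β values and the trend study over
5 seeds, with the family-scale diagnostic at 348 × 280 — sizes chosen to
keep the full suite in the low tens of seconds on one CPU while leaving
the Monte-Carlo assertions comfortably away from their thresholds.

## Known limitations

- Profile values are plug-in estimates; no small-sample entropy bias
  correction is applied (the corrected scores' global z-scoring absorbs
  the common bias, which is the analysis' operating assumption).
- The Zpx column-combination and ZNMI null reconstructions follow the
  cited score families at the level of published detail; variant formulas
  would shift inter-method agreement values.
- The greedy redundancy filter is order-dependent by design (stability
  over optimality).
- Correlation p-values assume independent pairs; pairs sharing a position
  are not independent, so p-values on pair-level correlations are
  approximate.
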