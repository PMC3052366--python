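"""Per-column information content of a protein family.

Generates a synthetic family with a conservation gradient, computes the
relative-entropy profile against the family background, smooths it with a
20-residue lowess span, and reports the above-mean regions plus the
positions where the two subfamily profiles differ by more than 2 sigma.
"""

import numpy as np

import coevostab as cs

spec = cs.SyntheticSpec(
    n_seqs=200,
    L=120,
    seed=11,
    # conserved "interior" stretch: columns 40..80 at low entropy
    conservation_profile=np.where(
        (np.arange(120) >= 40) & (np.arange(120) < 80), 0.8, 3.0
    ),
    gap_rate=0.02,
)
em = cs.generate_energy_matrix(spec)
aln = cs.generate_alignment(spec, em)

bg = cs.background_from_alignment(aln)
profile = cs.relative_entropy_profile(aln, bg)
smoothed = cs.loess_smooth(profile.values, span_residues=20)
regions = cs.above_mean_regions(smoothed, min_len=3)

print(f"family: {aln.n_seqs} sequences x {aln.length} positions")
print(f"mean information content: {profile.values.mean():.3f} bits")
print(f"above-mean regions (1-based): {regions.intervals}")

c23 = cs.relative_entropy_profile(aln.subfamily("C23"), bg)
n23 = cs.relative_entropy_profile(aln.subfamily("N23"), bg)
diff = cs.profile_difference(c23, n23)
outliers = cs.sigma_outliers(diff, k=2.0)
print(f"subfamily-divergent positions (>2 sigma): {outliers}")
print(
    "The above-mean regions recover the planted conserved stretch; with an\n"
    "even random subfamily split the difference profile flags only noise."
)
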