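"""Detecting planted covariation with corrected coevolution scores.

Builds an alignment with five strongly covarying column pairs hidden among
100 columns, scores all pairs with gap-scaled symmetric uncertainty, and
shows how the corrected scores (Zpx, ZRes, ZNMI) lift the planted pairs
above the 3-sigma threshold while the raw SU matrix is dominated by its
product-structured background.
"""

import coevostab as cs

spec = cs.planted_benchmark_spec(seed=7)
em = cs.generate_energy_matrix(spec)
aln = cs.generate_alignment(spec, em)
print(f"planted pairs (i, j, coupling): {spec.planted_pairs}")

stats = cs.pair_statistics(aln)
su = cs.su_matrix(stats)
print(f"SU background product correlation: "
      f"{cs.background_product_correlation(su):.3f}")

for sm in (cs.score_mip_zpx(su), cs.score_zres(su), cs.score_znmi(stats)):
    pl = cs.threshold_pairs(sm, k_sigma=3.0)
    rep = cs.recovery_report(spec, pl)
    top = ", ".join(f"({i},{j}) {s:.1f}" for i, j, s in pl.pairs[:5])
    print(f"{sm.method}: {len(pl)} pairs above 3 sigma, "
          f"recall {rep.recall:.2f}; top pairs: {top}")
print(
    "All five planted pairs top every corrected score; extra pairs at 3\n"
    "sigma are background fluctuations, which shrink at higher thresholds."
)
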