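"""The full pipeline from files on disk to a report bundle.

Writes a synthetic family (FASTA + subfamily labels + energy matrix) to a
temporary directory, runs the end-to-end pipeline, and lists the emitted
reports.  The same run is available from the shell as
``coevostab run config.json`` or via the ``profile``/``score``/``couple``
subcommands.
"""

import tempfile
from pathlib import Path

import numpy as np

import coevostab as cs
from coevostab.pipeline import RunConfig, run_pipeline

workdir = Path(tempfile.mkdtemp(prefix="coevostab_"))
spec = cs.SyntheticSpec(
    n_seqs=120, L=60, seed=3,
    planted_pairs=[(5, 41, 0.9), (12, 50, 0.85)],
    conservation_profile=np.random.default_rng(3).uniform(1.0, 3.0, 60),
)
em = cs.generate_energy_matrix(spec)
aln = cs.generate_alignment(spec, em)
cs.write_fasta_msa(aln, workdir / "family.fasta")
cs.write_energy_matrix(em, workdir / "energy.txt")
with open(workdir / "labels.tsv", "w") as fh:
    for rid, lab in zip(aln.ids, aln.labels):
        fh.write(f"{rid}\t{lab}\n")

cfg = RunConfig(
    msa_path=str(workdir / "family.fasta"),
    label_path=str(workdir / "labels.tsv"),
    energy_matrix_paths=[str(workdir / "energy.txt")],
    output_dir=str(workdir / "reports"),
    sigma_levels=[1, 2, 3, 4, 5],
)
bundle = run_pipeline(cfg)

print(f"config hash: {bundle['manifest']['config_hash']}")
print(f"SU background product correlation: "
      f"{bundle['background_correlation']:.3f}")
print("emitted reports:")
for f in sorted(Path(cfg.output_dir).iterdir()):
    print(f"  {f.name}")
pl = bundle["pair_lists"]["ZRes"][5]
print(f"ZRes pairs above 5 sigma: {[(i, j) for i, j, _ in pl.pairs]}")
print("Both planted pairs survive the strictest threshold; every number in")
print("the reports is reproducible by calling the library functions directly.")
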