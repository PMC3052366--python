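"""End-to-end orchestration: profiles -> coevolution scores -> stability.

``run_pipeline`` wires together the library modules in the order of the
analysis: read and reference-map the alignment, build entropy profiles
(family and per subfamily) with lowess smoothing and above-mean regions,
compute the gap-scaled SU matrix and its corrected scores, extract
threshold pair lists and per-position pair-count histograms, and — when an
energy matrix is supplied — stability/usage correlations and per-pair
stability magnitudes with score/stability correlation summaries.

Every emitted number is reproducible by calling the underlying module
functions directly; the pipeline adds no computation of its own.  Outputs
are plain TSV/JSON files plus a manifest recording the configuration hash,
so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .energy import (
    EnergyMatrix,
    merge_conformer_matrices,
    read_energy_matrix,
    stability_usage_correlation,
    subfamily_correlation_difference,
)
from .msa import (
    Alignment,
    attach_labels,
    filter_redundancy,
    frequency_matrix,
    map_to_reference,
    read_fasta_msa,
    read_labels_tsv,
)
from .pair_stability import (
    classify_mechanism,
    pair_stability_records,
    score_stability_correlation,
)
from .profile import (
    above_mean_regions,
    background_from_alignment,
    loess_smooth,
    profile_difference,
    relative_entropy_profile,
    sigma_outliers,
)
from .scores import (
    background_product_correlation,
    histogram_entropy_correlation,
    pair_count_histogram,
    pair_statistics,
    score_mip_zpx,
    score_znmi,
    score_zres,
    su_matrix,
    threshold_pairs,
)

logger = logging.getLogger(__name__)

_SCORERS = ("Zpx", "ZRes", "ZNMI")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (JSON-serialisable)."""

    msa_path: str
    output_dir: str
    label_path: str | None = None
    label_regex: str | None = None
    reference_id: str | None = None
    energy_matrix_paths: list[str] = field(default_factory=list)
    energy_matrix_weights: list[float] | None = None
    identity_ceilings: list[float] = field(default_factory=list)
    methods: list[str] = field(default_factory=lambda: list(_SCORERS))
    sigma_levels: list[float] = field(default_factory=lambda: [1, 2, 3, 4, 5])
    pseudocount_mass: float = 1.0
    loess_span: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if sorted(self.sigma_levels) != list(self.sigma_levels) or any(
            s <= 0 for s in self.sigma_levels
        ):
            raise ValueError("sigma_levels must be positive and sorted")
        if self.energy_matrix_weights is not None and len(
            self.energy_matrix_weights
        ) != len(self.energy_matrix_paths):
            raise ValueError("one weight per energy matrix required")
        unknown = set(self.methods) - set(_SCORERS)
        if unknown:
            raise ValueError(f"unknown scoring methods: {sorted(unknown)}")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_alignment(cfg: RunConfig) -> Alignment:
    aln = read_fasta_msa(cfg.msa_path)
    if cfg.label_path:
        aln = attach_labels(aln, mapping=read_labels_tsv(cfg.label_path))
    elif cfg.label_regex:
        aln = attach_labels(aln, id_regex=cfg.label_regex)
    if cfg.reference_id:
        aln = map_to_reference(aln, cfg.reference_id)
    return aln


def _load_energy_matrix(cfg: RunConfig) -> EnergyMatrix | None:
    if not cfg.energy_matrix_paths:
        return None
    mats = [read_energy_matrix(p) for p in cfg.energy_matrix_paths]
    if len(mats) == 1:
        return mats[0]
    weights = cfg.energy_matrix_weights or [1.0] * len(mats)
    return merge_conformer_matrices(mats, weights)


def _score_matrices(aln: Alignment, methods: list[str]):
    stats = pair_statistics(aln)
    su = su_matrix(stats)
    out = {}
    for m in methods:
        if m == "Zpx":
            out[m] = score_mip_zpx(su)
        elif m == "ZRes":
            out[m] = score_zres(su)
        elif m == "ZNMI":
            out[m] = score_znmi(stats)
    return su, out


def _tsv_header(fh, cfg: RunConfig, **extra) -> None:
    tags = " ".join(f"{k}={v}" for k, v in extra.items())
    fh.write(f"# coevostab config={cfg.config_hash()} {tags}\n".rstrip() + "\n")


def _write_tsv(df: pd.DataFrame, path: Path, cfg: RunConfig, **extra) -> None:
    with open(path, "w") as fh:
        _tsv_header(fh, cfg, **extra)
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis and write its report bundle.

    Returns the in-memory bundle: profiles, score matrices, per-method
    pair lists and correlation summaries.  With no energy matrix the
    stability stages are skipped (with a logged notice) and scoring still
    runs.
    """
    t0 = time.time()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    aln = _load_alignment(cfg)
    em = _load_energy_matrix(cfg)

    bundle: dict = {"alignment": aln, "energy_matrix": em}

    # --- entropy profiles (family and subfamilies) -------------------------
    bg = background_from_alignment(aln, cfg.pseudocount_mass)
    profile = relative_entropy_profile(aln, bg, cfg.pseudocount_mass)
    smoothed = loess_smooth(profile.values, cfg.loess_span)
    regions = above_mean_regions(smoothed)
    prof_df = pd.DataFrame(
        {
            "position": profile.positions,
            "value": profile.values,
            "smoothed": smoothed,
            "n_ungapped": profile.n_ungapped,
            "all_gap": profile.flags.astype(int),
        }
    )
    _write_tsv(prof_df, outdir / "profile_family.tsv", cfg, stage="profile")
    with open(outdir / "regions_family.json", "w") as fh:
        json.dump({"intervals": regions.intervals}, fh)
    bundle.update(profile=profile, smoothed=smoothed, regions=regions)

    sub_profiles = {}
    if aln.labels is not None:
        for lab in sorted(set(aln.labels)):
            sub = aln.subfamily(lab)
            sub_profiles[lab] = relative_entropy_profile(sub, bg, cfg.pseudocount_mass)
        if len(sub_profiles) == 2:
            la, lb = sorted(sub_profiles)
            diff = profile_difference(sub_profiles[la], sub_profiles[lb])
            flags = sigma_outliers(diff, 2.0)
            diff_df = pd.DataFrame(
                {
                    "position": profile.positions,
                    "difference": diff,
                    "outlier_2sigma": [
                        int(p in set(flags)) for p in profile.positions
                    ],
                }
            )
            _write_tsv(
                diff_df, outdir / "profile_difference.tsv", cfg,
                stage="profile", pair=f"{la}-{lb}",
            )
            bundle["profile_difference"] = diff
    bundle["subfamily_profiles"] = sub_profiles

    # --- coevolution scores ------------------------------------------------
    su, matrices = _score_matrices(aln, cfg.methods)
    bundle["su_matrix"] = su
    bundle["score_matrices"] = matrices
    bundle["background_correlation"] = background_product_correlation(su)
    conserved = su.excluded
    pair_lists: dict[str, dict[float, object]] = {}
    hist_corr_rows = []
    for m, sm in matrices.items():
        df = pd.DataFrame(sm.values, columns=[str(p) for p in sm.positions])
        _write_tsv(df, outdir / f"matrix_{m}.tsv", cfg, stage="score", method=m)
        pair_lists[m] = {}
        for k in cfg.sigma_levels:
            pl = threshold_pairs(sm, k)
            pair_lists[m][k] = pl
            counts = pair_count_histogram(pl, aln.length, aln.positions)
            r, p = histogram_entropy_correlation(counts, profile, conserved)
            hist_corr_rows.append(
                {"method": m, "sigma": k, "n_pairs": len(pl), "r": r, "p": p}
            )
            pl_df = pd.DataFrame(pl.pairs, columns=["i", "j", "score"])
            _write_tsv(
                pl_df, outdir / f"pairs_{m}_{k:g}sigma.tsv", cfg,
                stage="score", method=m, sigma=k,
            )
    hist_df = pd.DataFrame(hist_corr_rows)
    _write_tsv(hist_df, outdir / "histogram_entropy_correlation.tsv", cfg, stage="score")
    bundle["pair_lists"] = pair_lists
    bundle["histogram_entropy_correlation"] = hist_df

    # --- stability stages --------------------------------------------------
    if em is None:
        logger.warning("no energy matrix supplied; stability stages skipped")
    elif em.length != aln.length:
        raise ValueError("energy matrix length does not match the alignment")
    else:
        freqs = frequency_matrix(aln)
        report = stability_usage_correlation(em, freqs)
        rep_df = pd.DataFrame(
            {
                "position": report.positions,
                "r": report.r,
                "p": report.p,
                "flagged": report.flagged.astype(int),
            }
        )
        _write_tsv(rep_df, outdir / "stability_usage.tsv", cfg, stage="stability")
        bundle["stability_usage"] = report
        if aln.labels is not None and len(set(aln.labels)) == 2:
            la, lb = sorted(set(aln.labels))
            rep_a = stability_usage_correlation(em, frequency_matrix(aln.subfamily(la)))
            rep_b = stability_usage_correlation(em, frequency_matrix(aln.subfamily(lb)))
            diff, flagged = subfamily_correlation_difference(rep_a, rep_b)
            sub_df = pd.DataFrame(
                {
                    "position": report.positions,
                    "difference": diff,
                    "outlier_2sigma": [int(p in set(flagged)) for p in report.positions],
                }
            )
            _write_tsv(
                sub_df, outdir / "stability_usage_difference.tsv", cfg,
                stage="stability", pair=f"{la}-{lb}",
            )
            bundle["stability_usage_difference"] = (diff, flagged)

        summaries = []
        for m, levels in pair_lists.items():
            for k, pl in levels.items():
                records = pair_stability_records(aln, em, pl)
                labels = classify_mechanism(records)
                rec_df = pd.DataFrame(
                    {
                        "i": [r.i for r in records],
                        "j": [r.j for r in records],
                        "score": [r.score for r in records],
                        "ddg_sum": [r.ddg_sum for r in records],
                        "ddg_absdiff": [r.ddg_absdiff for r in records],
                        "n_seqs": [r.n_seqs for r in records],
                        "opposite": [int(r.opposite) for r in records],
                        "mechanism": labels,
                    }
                )
                _write_tsv(
                    rec_df, outdir / f"pair_stability_{m}_{k:g}sigma.tsv", cfg,
                    stage="stability", method=m, sigma=k,
                )
                if len(records) >= 3:
                    summaries.append(
                        dataclasses.asdict(
                            score_stability_correlation(records, k, method=m)
                        )
                    )
        with open(outdir / "score_stability_summaries.json", "w") as fh:
            json.dump(summaries, fh, indent=1)
        bundle["score_stability_summaries"] = summaries

    manifest = {
        "config": dataclasses.asdict(cfg),
        "config_hash": cfg.config_hash(),
        "version": __version__,
        "n_seqs": aln.n_seqs,
        "length": aln.length,
        "excluded_columns": sorted(conserved),
        "runtime_s": round(time.time() - t0, 3),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    bundle["manifest"] = manifest
    return bundle


def sweep_redundancy(cfg: RunConfig, method: str = "ZRes") -> pd.DataFrame:
    """Pair-count statistics across a sweep of identity ceilings.

    For each ceiling the alignment is greedily reduced, re-scored with one
    corrected method, and the unique-pair counts per sigma level plus the
    5-sigma/1-sigma contrast ratio are tabulated.  A ceiling that empties
    the alignment is recorded as an empty row.
    """
    if not cfg.identity_ceilings:
        raise ValueError("identity_ceilings must be non-empty")
    aln = _load_alignment(cfg)
    rows = []
    for ceiling in cfg.identity_ceilings:
        reduced = filter_redundancy(aln, ceiling)
        row: dict = {"ceiling": ceiling, "n_seqs": reduced.n_seqs}
        if reduced.n_seqs < 2:
            rows.append(row)
            continue
        _, mats = _score_matrices(reduced, [method])
        sm = mats[method]
        counts = {}
        for k in cfg.sigma_levels:
            counts[k] = len(threshold_pairs(sm, k))
            row[f"pairs_{k:g}sigma"] = counts[k]
        lo, hi = min(cfg.sigma_levels), max(cfg.sigma_levels)
        row["contrast_ratio"] = (
            counts[hi] / counts[lo] if counts.get(lo) else float("nan")
        )
        rows.append(row)
    df = pd.DataFrame(rows)
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_tsv(df, outdir / f"redundancy_sweep_{method}.tsv", cfg, stage="sweep")
    return df
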