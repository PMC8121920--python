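"""End-to-end orchestration of the synthetic-cohort analysis.

One config drives simulate -> test -> {sharing, motifs, expression};
every output is recorded in a manifest with a content hash so identical
config + seed reproduce identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import imbalance, motif_profiles, sharing_context, synthetic_data
from .imbalance import CallThresholds, PoolingScheme

log = logging.getLogger("allelix")


@dataclass
class PipelineConfig:
    outdir: str = "allelix_out"
    seed: int = 1
    n_snvs: int = 20_000
    level: str = "cell_type"
    fdr: float = 0.10
    ratio: float = 0.70
    min_reads: int = 30
    rho: float = 0.03
    fraction_causal: float = 0.05
    stages: tuple[str, ...] = ("simulate", "test", "share", "motifs")

    def __post_init__(self):
        if not 0 < self.fdr < 1:
            raise ValueError(f"fdr must be in (0,1), got {self.fdr}")
        if not 0.5 <= self.ratio < 1:
            raise ValueError(f"ratio must be in [0.5,1), got {self.ratio}")
        if self.min_reads < 1:
            raise ValueError("min_reads must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in dependency order; return the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "thresholds": {"fdr": config.fdr, "ratio": config.ratio,
                       "min_reads": config.min_reads},
        "files": {}, "timing_s": {},
    }
    thresholds = CallThresholds(fdr=config.fdr, ratio=config.ratio,
                                min_reads=config.min_reads)
    log.info("thresholds: fdr=%s ratio=%s min_reads=%s",
             config.fdr, config.ratio, config.min_reads)

    def record(name: str, path: Path):
        manifest["files"][name] = {"path": str(path), "sha256": _sha256(path)}

    t0 = time.time()
    cohort = None
    if "simulate" in config.stages:
        cfg = synthetic_data.SimConfig(seed=config.seed, n_snvs=config.n_snvs,
                                       rho=config.rho,
                                       fraction_causal=config.fraction_causal)
        cohort = synthetic_data.simulate_cohort(cfg)
        cohort.counts.to_csv(out / "counts.tsv", sep="\t", index=False)
        cohort.snvs.to_csv(out / "snvs.tsv", sep="\t", index=False)
        cohort.true_effects.to_csv(out / "true_effects.tsv", sep="\t", index=False)
        record("counts", out / "counts.tsv")
        record("snvs", out / "snvs.tsv")
        record("true_effects", out / "true_effects.tsv")
        manifest["timing_s"]["simulate"] = round(time.time() - t0, 2)
    if cohort is None:
        raise RuntimeError("stage 'test' requires stage 'simulate' outputs")

    calls = None
    if "test" in config.stages:
        t0 = time.time()
        scheme = PoolingScheme.from_frame(cohort.scheme_frame())
        pooled = imbalance.pool_counts(cohort.counts, scheme, config.level)
        nulls = imbalance.fit_all_nulls(pooled, fallback_rho=config.rho)
        calls = imbalance.call_imbalance(pooled, nulls, thresholds, config.level)
        calls.to_csv(out / "calls.tsv", sep="\t", index=False)
        record("calls", out / "calls.tsv")
        manifest["timing_s"]["test"] = round(time.time() - t0, 2)

    if "share" in config.stages and calls is not None:
        t0 = time.time()
        sharing = sharing_context.pairwise_sharing(calls)
        sharing.to_csv(out / "sharing.tsv", sep="\t")
        record("sharing", out / "sharing.tsv")
        curve = sharing_context.adjacent_ratio_correlation(
            calls, cohort.snvs[["snv_id", "chrom", "pos"]], seed=config.seed)
        curve.to_frame().to_csv(out / "adjacent_correlation.tsv", sep="\t", index=False)
        record("adjacent_correlation", out / "adjacent_correlation.tsv")
        manifest["timing_s"]["share"] = round(time.time() - t0, 2)

    if "motifs" in config.stages and calls is not None:
        t0 = time.time()
        assigns = motif_profiles.snv_motif_assignments(
            cohort.snvs, cohort.motif_matches)
        profiles = []
        for m in cohort.motifs.itertuples(index=False):
            prof = motif_profiles.build_position_profile(
                assigns, calls, m.motif_id, int(m.width))
            df = prof.to_frame()
            df["qc_pass"] = motif_profiles.motif_qc_filter(prof)
            profiles.append(df)
        pd.concat(profiles, ignore_index=True).to_csv(
            out / "motif_profiles.tsv", sep="\t", index=False)
        record("motif_profiles", out / "motif_profiles.tsv")
        frac, num, den = motif_profiles.overall_motif_overlap(
            calls, cohort.snvs, cohort.motif_matches)
        (out / "motif_overlap.json").write_text(json.dumps(
            {"fraction": frac, "n_in_motif": num, "n_imbalanced": den}))
        record("motif_overlap", out / "motif_overlap.json")
        manifest["timing_s"]["motifs"] = round(time.time() - t0, 2)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    log.info("pipeline complete: %d files", len(manifest["files"]))
    return manifest
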