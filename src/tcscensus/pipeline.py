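"""End-to-end pipeline: annotations in, census reports out.

A :class:`RunConfig` (usually loaded from YAML) names the inputs and the
tunables of every stage; :func:`run_pipeline` executes the stages in
dependency order and writes per-gene calls, orphan reports, per-genome
summaries, cohort comparisons, cluster assignments and power-law fits into
one output directory, each table stamped with the tool version, a config
hash, and the seed. The config is echoed verbatim into the output directory
so any run can be reproduced from its artifacts alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import PfamRuleSet, calls_to_frame, classify_genome
from .cluster import build_feature_matrix, scale_features, select_k_by_silhouette
from .io import metadata_to_frame, read_genome_annotation, read_metadata
from .orphans import find_orphans, genome_track, track_to_bed
from .powerlaw import PowerLawModel
from .stats import (
    summaries_to_frame,
    summarize_genome,
    two_sample_ttest,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclasses.dataclass
class RunConfig:
    """Everything a pipeline run needs; ``seed`` is mandatory for any
    stochastic stage (clustering, bootstrap)."""

    outdir: str
    seed: int | None = None
    # inputs: list of (gene_table, domain_table) paths, plus metadata table
    genomes: list[tuple[str, str]] = dataclasses.field(default_factory=list)
    metadata_path: str | None = None
    abundance_path: str | None = None
    environment_path: str | None = None
    ruleset: dict | None = None
    orphan_multiplier: float = 4.0
    scaling: str = "minmax"
    k_range: tuple[int, int] = (2, 10)
    test_tails: str = "two"
    n_boot: int = 10_000
    compare_metric: str = "hpk_per_100_genes"
    compare_groups: tuple[str, str] = ("copiotroph", "oligotroph")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["genomes"] = [tuple(g) for g in raw.get("genomes", [])]
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        if "compare_groups" in raw:
            raw["compare_groups"] = tuple(raw["compare_groups"])
        return cls(**raw)

    def validate(self) -> None:
        # comparison (bootstrap CIs) and clustering both need the metadata table
        wants_stochastic = self.metadata_path is not None
        if wants_stochastic and self.seed is None:
            raise ValueError("config must set a seed when stochastic stages (clustering/bootstrap) run")
        if self.orphan_multiplier <= 0:
            raise ValueError("orphan_multiplier must be > 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _config_hash(config: RunConfig) -> str:
    # outdir is where results land, not what they are: identical analysis
    # configs hash identically regardless of destination
    d = {k: v for k, v in config.to_dict().items() if k != "outdir"}
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _stamp(config: RunConfig, cfg_hash: str) -> str:
    return f"# tcscensus {__version__} | config {cfg_hash} | seed {config.seed}\n"


def _write_tsv(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> Path:
    """Run every applicable stage; returns the output directory.

    Stage errors after partial progress leave prior outputs in place plus
    an ``error_manifest.json`` describing the failure, then re-raise.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = _config_hash(config)
    stamp = _stamp(config, cfg_hash)
    with open(outdir / "config_echo.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    completed: list[str] = []
    try:
        rules = PfamRuleSet.from_config(config.ruleset or {})
        all_calls, all_orphans, summaries = [], [], []
        for gene_path, domain_path in config.genomes:
            ann = read_genome_annotation(gene_path, domain_path)
            calls, counts = classify_genome(ann, rules)
            orphans = find_orphans(calls, ann, multiplier=config.orphan_multiplier)
            summaries.append(summarize_genome(calls, orphans, ann, counts))
            cf = calls_to_frame(calls)
            cf.insert(0, "genome_id", ann.genome_id)
            all_calls.append(cf)
            orphan_by_id = {o.gene_id: o for o in orphans}
            of = genome_track(calls, orphans)
            of.insert(0, "genome_id", ann.genome_id)
            of["nearest_tcs_distance_bp"] = [
                orphan_by_id[g].nearest_tcs_distance_bp for g in of["gene_id"]
            ]
            of["threshold_bp"] = [orphan_by_id[g].threshold_bp for g in of["gene_id"]]
            all_orphans.append(of)
            track_to_bed(genome_track(calls, orphans), ann, outdir / f"{ann.genome_id}.tcs_track.bed")
            logger.info("processed genome %s: %s", ann.genome_id, tuple(counts))
        if all_calls:
            _write_tsv(pd.concat(all_calls, ignore_index=True), outdir / "gene_calls.tsv", stamp)
            _write_tsv(pd.concat(all_orphans, ignore_index=True), outdir / "orphan_report.tsv", stamp)
            _write_tsv(summaries_to_frame(summaries), outdir / "genome_summaries.tsv", stamp)
            completed.append("classify+orphans+summarize")

        meta_df = None
        if config.metadata_path:
            meta_df = metadata_to_frame(read_metadata(config.metadata_path))

        if summaries and meta_df is not None:
            sdf = summaries_to_frame(summaries).merge(meta_df, on="genome_id", how="left")
            a_lab, b_lab = config.compare_groups
            a = sdf.loc[sdf["lifestyle"] == a_lab, config.compare_metric].dropna()
            b = sdf.loc[sdf["lifestyle"] == b_lab, config.compare_metric].dropna()
            if len(a) >= 2 and len(b) >= 2:
                res = two_sample_ttest(
                    a, b, tails=config.test_tails, labels=(a_lab, b_lab),
                    ci_seed=config.seed, n_boot=config.n_boot,
                )
                with open(outdir / "cohort_report.json", "w") as fh:
                    json.dump(dataclasses.asdict(res), fh, indent=2)
                completed.append("compare")

            fm = build_feature_matrix(sdf[["genome_id", "hpk_per_100_genes"]], meta_df)
            if fm.features.shape[0] > max(3, config.k_range[0]):
                scaled = scale_features(fm, method=config.scaling)
                kmax = min(config.k_range[1], fm.features.shape[0] - 1)
                result = select_k_by_silhouette(
                    scaled, range(config.k_range[0], kmax + 1), seed=config.seed
                )
                _write_tsv(result.to_frame(), outdir / "cluster_assignments.tsv", stamp)
                with open(outdir / "silhouette_report.json", "w") as fh:
                    json.dump(
                        {
                            "selected_k": result.k,
                            "mean_silhouette": result.mean_silhouette,
                            "per_k": {str(k): v for k, v in result.per_k_silhouettes.items()},
                            "scaling": scaled.scaling_record,
                            "seed": result.seed,
                        },
                        fh,
                        indent=2,
                    )
                completed.append("cluster")

        if config.abundance_path and config.environment_path:
            adf = pd.read_csv(config.abundance_path, sep="\t")
            edf = pd.read_csv(config.environment_path, sep="\t")
            fit = PowerLawModel.from_profiles(adf, edf).fit()
            with open(outdir / "powerlaw_report.json", "w") as fh:
                json.dump(dataclasses.asdict(fit), fh, indent=2)
            completed.append("powerlaw")
    except Exception as exc:
        with open(outdir / "error_manifest.json", "w") as fh:
            json.dump({"completed_stages": completed, "error": str(exc), "config": cfg_hash}, fh, indent=2)
        raise

    with open(outdir / "manifest.json", "w") as fh:
        json.dump({"completed_stages": completed, "config": cfg_hash, "seed": config.seed, "version": __version__}, fh, indent=2)
    return outdir
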