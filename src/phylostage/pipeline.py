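"""Top-level pipeline: files in, validated report + manifest out.

Order of operations mirrors the analysis it packages: load and cross-validate
inputs, normalize, compute the index profile, run the flat-line permutation
test, run the hourglass tests when the profile deviates from flat (gating is
configurable), and — when a DEG table is supplied — run the phylostratum
enrichment analysis.  Every output is deterministic given the inputs and the
seed; the manifest records input hashes, the full configuration and package
version so a run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from . import __version__
from .agemap import load_age_map, load_divergence_map, rank_deciles
from .enrichment import median_log2fc_by_stratum
from .exceptions import ValidationError
from .io import (
    load_staged_expression,
    read_deg_table,
    write_enrichment,
    write_json,
    write_profile,
)
from .model import StratumEnrichment, TranscriptomeIndex
from .pattern_tests import StageModules

logger = logging.getLogger("phylostage")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run (YAML-loadable)."""

    expr: str
    meta: str
    ages: str | None = None
    dnds: str | None = None
    deg: str | None = None
    out_dir: str = "phylostage_out"
    index_kind: str = "TAI"
    aggregation: str = "mean-expression"
    modules: str = "I:II,III:IV"
    B: int = 1000
    n_bootstrap: int = 10_000
    seed: int = 0
    scale: float = 1e6
    log_transform: bool = False
    alpha: float = 0.05
    gate_hourglass: bool = True

    def __post_init__(self) -> None:
        if self.index_kind not in ("TAI", "TDI"):
            raise ValidationError(f"index_kind must be TAI or TDI, got {self.index_kind!r}")
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.B < 100:
            raise ValidationError(f"B must be >= 100, got {self.B}")
        if self.n_bootstrap < 100:
            raise ValidationError(f"n_bootstrap must be >= 100, got {self.n_bootstrap}")
        if self.index_kind == "TAI" and self.ages is None:
            raise ValidationError("index_kind TAI requires an ages table")
        if self.index_kind == "TDI" and self.dnds is None:
            raise ValidationError("index_kind TDI requires a dN/dS table")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _result_entry(obj) -> dict:
    return obj if isinstance(obj, dict) else obj.to_dict()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write report files under ``out_dir``.

    Returns the report dict.  Raises :class:`ValidationError` on any
    cross-file inconsistency (message names the file and identifier).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    data = load_staged_expression(config.expr, config.meta)
    logger.info("loaded %d genes x %d samples", data.n_genes, data.n_samples)

    if config.index_kind == "TAI":
        strata = load_age_map(config.ages)
    else:
        strata = rank_deciles(load_divergence_map(config.dnds))

    model = TranscriptomeIndex(
        data,
        strata,
        aggregation=config.aggregation,
        scale=config.scale,
        log_transform=config.log_transform,
    )
    results = model.fit()
    logger.info(
        "%s profile: %d genes used, %d dropped (no annotation)",
        config.index_kind,
        results.profile.n_genes_used,
        results.profile.n_genes_dropped,
    )

    modules = StageModules.from_spec(config.modules)
    tests = results.test_patterns(
        modules=modules,
        B=config.B,
        seed=config.seed,
        alpha=config.alpha,
        gated=config.gate_hourglass,
    )

    report: dict = {
        "index_kind": config.index_kind,
        "profile": results.profile.to_dict(),
        "pattern_tests": {k: _result_entry(v) for k, v in tests.items()},
        "config": config.to_dict(),
    }

    write_profile(results.profile, out_dir / "profile.tsv", out_dir / "profile.json")
    write_json(report["pattern_tests"], out_dir / "pattern_tests.json")

    inputs = {"expr": config.expr, "meta": config.meta}
    if config.ages:
        inputs["ages"] = config.ages
    if config.dnds:
        inputs["dnds"] = config.dnds

    if config.deg is not None:
        if config.ages is None:
            raise ValidationError("enrichment requires an ages table")
        deg_table = read_deg_table(config.deg)
        inputs["deg"] = config.deg
        ages = strata if config.index_kind == "TAI" else load_age_map(config.ages)
        enrichment = StratumEnrichment(deg_table.all_genes(), ages).fit(
            n_bootstrap=config.n_bootstrap, seed=config.seed
        )
        medians = median_log2fc_by_stratum(deg_table, ages)
        report["enrichment"] = enrichment.result.to_dict()
        report["median_log2fc_by_stratum"] = {
            str(stratum): {
                stage: (None if medians.isna().loc[stratum, stage] else float(medians.loc[stratum, stage]))
                for stage in medians.columns
            }
            for stratum in medians.index
        }
        write_enrichment(
            enrichment.result, out_dir / "enrichment.tsv", out_dir / "enrichment.json"
        )
        medians.to_csv(out_dir / "median_log2fc_by_stratum.tsv", sep="\t")

    # out_dir is where the manifest lives, not part of the analysis identity:
    # drop it so runs into different directories stay bit-identical
    manifest_config = {k: v for k, v in config.to_dict().items() if k != "out_dir"}
    manifest = {
        "phylostage_version": __version__,
        "seed": config.seed,
        "config": manifest_config,
        "inputs": {
            name: {"path": str(path), "sha256": _sha256(path)}
            for name, path in inputs.items()
        },
        "outputs": sorted(p.name for p in out_dir.iterdir() if p.name != "manifest.json"),
    }
    write_json(manifest, out_dir / "manifest.json")
    report["manifest"] = manifest
    return report
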