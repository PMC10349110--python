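"""Pipeline orchestration: one config in, a report bundle out.

A run takes either a real-data block (paths to a ratings CSV and item-key
CSV) or a synthetic block (generator settings) — never both — and writes a
bundle of CSV tables and figures: group accuracy, per-observer AUC, SDT
summaries, response profiles, correlation matrices with heatmaps, fusion
tables, and a JSON manifest recording seeds and the analysis toggles in
force, sufficient to re-run the bundle bit-identically.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from . import __version__
from .datamodel import (ItemKey, RatingMatrix, load_item_key, load_ratings,
                        validate_study, write_item_key, write_ratings)
from .errors import ConfigError
from .fusion import FusionConfig, fusion_report, run_fusion
from .roc import group_auc_summary, group_summary_frame, observer_auc_table
from .sdt import profile_frame, response_profile, sdt_summary, sdt_summary_frame
from .similarity import (block_agreement, block_agreement_frame,
                         correlation_matrix, heatmap_export)
from .simulate import (SyntheticConfig, generate_study, human_subset,
                       study_cohort_config)

log = logging.getLogger(__name__)

ALL_STAGES = ("accuracy", "sdt", "similarity", "fusion")


@dataclass
class PipelineConfig:
    out_dir: Path
    ratings_path: Path | None = None
    key_path: Path | None = None
    value_kind: str = "ordinal_11pt"
    synthetic: SyntheticConfig | None = None
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    inconclusive_policy: str = "exclude"
    correction_rule: str = "loglinear"
    fusion_compositions: list[dict[str, Any]] = field(default_factory=list)
    fusion_n_samples: int = 1000

    def __post_init__(self) -> None:
        real = self.ratings_path is not None or self.key_path is not None
        if real and self.synthetic is not None:
            raise ConfigError("give either real-data paths or a synthetic "
                              "block, not both")
        if real and (self.ratings_path is None or self.key_path is None):
            raise ConfigError("real-data runs need both ratings_path and key_path")
        if not real and self.synthetic is None:
            raise ConfigError("no input: set data paths or a synthetic block")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages {sorted(unknown)}")


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML (or JSON — YAML is a superset) pipeline config."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    data = raw.get("data", {}) or {}
    syn_block = raw.get("synthetic")
    synthetic = None
    if syn_block is not None:
        if syn_block == "study_cohort" or syn_block.get("preset") == "study_cohort":
            seed = raw.get("seed", 0) if syn_block == "study_cohort" \
                else syn_block.get("seed", raw.get("seed", 0))
            synthetic = study_cohort_config(seed=seed)
        else:
            raise ConfigError("synthetic block must use preset: study_cohort; "
                              "build custom SyntheticConfig objects in code")
    fus = raw.get("fusion", {}) or {}
    return PipelineConfig(
        out_dir=Path(raw.get("out_dir", "out")),
        ratings_path=Path(data["ratings_path"]) if "ratings_path" in data else None,
        key_path=Path(data["key_path"]) if "key_path" in data else None,
        value_kind=data.get("value_kind", "ordinal_11pt"),
        synthetic=synthetic,
        stages=tuple(raw.get("stages", ALL_STAGES)),
        seed=raw.get("seed", 0),
        inconclusive_policy=raw.get("inconclusive_policy", "exclude"),
        correction_rule=raw.get("correction_rule", "loglinear"),
        fusion_compositions=fus.get("compositions", []),
        fusion_n_samples=fus.get("n_samples", 1000),
    )


def default_fusion_compositions(matrix: RatingMatrix) -> list[dict[str, Any]]:
    """Singleton, pair and triplet compositions over the expert groups and
    the group-wise best DNNs, mirroring the standard fusion comparison."""
    comps: list[dict[str, Any]] = []
    groups = set(matrix.groups.unique())
    experts = [g for g in ("super_recognizer", "forensic_examiner") if g in groups]
    for g in experts:
        comps.append({g: 1})
    for i, a in enumerate(experts):
        for b in experts[i:]:
            comps.append({a: 1, b: 1} if a != b else {a: 2})
    if "dnn" in groups:
        comps.append({"dnn": 1})
        comps.append({"dnn": 2})
        for g in experts:
            comps.append({g: 1, "dnn": 1})
            comps.append({g: 2, "dnn": 1})
    return comps


@dataclass
class ReportBundle:
    out_dir: Path
    tables: dict[str, Path]
    figures: dict[str, Path]
    manifest_path: Path


def _resolve_inputs(config: PipelineConfig,
                    ) -> tuple[RatingMatrix, list[ItemKey]]:
    if config.synthetic is not None:
        matrix, keys, truth = generate_study(config.synthetic)
        return matrix, keys
    matrix = load_ratings(config.ratings_path, config.value_kind)
    keys = load_item_key(config.key_path)
    return matrix, keys


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables: dict[str, Path] = {}
    figures: dict[str, Path] = {}

    t0 = time.perf_counter()
    matrix, keys = _resolve_inputs(config)
    if config.synthetic is not None:
        write_ratings(matrix, out / "ratings.csv")
        write_item_key(keys, out / "key.csv")
        tables["ratings"] = out / "ratings.csv"
        tables["key"] = out / "key.csv"
    report = validate_study(matrix, keys)
    (out / "validation.txt").write_text(str(report) + "\n")
    tables["validation"] = out / "validation.txt"
    log.info("inputs resolved and validated in %.2fs", time.perf_counter() - t0)

    has_dnn = "dnn" in set(matrix.groups.unique())
    humans = human_subset(matrix) if has_dnn else matrix

    if "accuracy" in config.stages:
        t = time.perf_counter()
        summaries = group_auc_summary(matrix, keys)
        group_summary_frame(summaries).to_csv(out / "group_auc.csv", index=False)
        observer_auc_table(matrix, keys).to_csv(out / "observer_auc.csv", index=False)
        tables["group_auc"] = out / "group_auc.csv"
        tables["observer_auc"] = out / "observer_auc.csv"
        log.info("accuracy stage in %.2fs", time.perf_counter() - t)

    if "sdt" in config.stages:
        t = time.perf_counter()
        sdt = sdt_summary(humans, keys, config.inconclusive_policy,
                          config.correction_rule)
        sdt_summary_frame(sdt).to_csv(out / "sdt_summary.csv", index=False)
        profiles = response_profile(humans, keys, by="group")
        profile_frame(profiles).to_csv(out / "response_profiles.csv", index=False)
        tables["sdt_summary"] = out / "sdt_summary.csv"
        tables["response_profiles"] = out / "response_profiles.csv"
        log.info("sdt stage in %.2fs", time.perf_counter() - t)

    if "similarity" in config.stages:
        t = time.perf_counter()
        blocks = []
        for tt in ("same", "different"):
            corr = correlation_matrix(matrix, keys, tt)
            corr.rho.to_csv(out / f"correlation_{tt}.csv")
            tables[f"correlation_{tt}"] = out / f"correlation_{tt}.csv"
            fig = heatmap_export(corr, out / f"heatmap_{tt}.png", matrix.groups)
            figures[f"heatmap_{tt}"] = fig
            blocks.extend(block_agreement(corr, matrix.groups))
            coarse = matrix.groups.map(lambda g: "dnn" if g == "dnn" else "human")
            blocks.extend(block_agreement(corr, coarse,
                                          pairs=[("dnn", "human")]))
        block_agreement_frame(blocks).to_csv(out / "block_agreement.csv",
                                             index=False)
        tables["block_agreement"] = out / "block_agreement.csv"
        log.info("similarity stage in %.2fs", time.perf_counter() - t)

    if "fusion" in config.stages:
        t = time.perf_counter()
        comps = config.fusion_compositions or default_fusion_compositions(matrix)
        results = []
        for i, comp in enumerate(comps):
            fc = FusionConfig(composition=comp,
                              n_samples=config.fusion_n_samples,
                              seed=config.seed + i)
            results.append(run_fusion(matrix, keys, fc))
        fusion_report(results).to_csv(out / "fusion.csv", index=False)
        tables["fusion"] = out / "fusion.csv"
        log.info("fusion stage in %.2fs", time.perf_counter() - t)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "inconclusive_policy": config.inconclusive_policy,
        "correction_rule": config.correction_rule,
        "input": ("synthetic" if config.synthetic is not None
                  else {"ratings_path": str(config.ratings_path),
                        "key_path": str(config.key_path),
                        "value_kind": config.value_kind}),
        "synthetic_seed": (config.synthetic.seed
                           if config.synthetic is not None else None),
        "fusion_n_samples": config.fusion_n_samples,
        "tables": {k: str(v) for k, v in tables.items()},
        "figures": {k: str(v) for k, v in figures.items()},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return ReportBundle(out, tables, figures, manifest_path)
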