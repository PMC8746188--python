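"""Configuration-driven orchestration of cohort generation and analyses.

A run config (YAML or JSON) names a cohort source (a directory written by
:func:`clsm.cohort.save_cohort` or ``synthetic`` plus generator parameters),
a list of analyses, an output directory and a master seed. ``run_pipeline``
executes every analysis, writes per-analysis result tables and a JSON run
manifest with content hashes, and is bit-reproducible from config + seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Union

import yaml

import clsm
from clsm.analyses import (
    AnalysisConfig,
    CovariateMode,
    functional_edge_analysis,
    region_lsm,
    structural_edge_analysis,
)
from clsm.cohort import CohortConfig, CohortDataset, generate_cohort, load_cohort
from clsm.glm import PermutationConfig
from clsm.io import file_sha256

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "load_run_config"]

log = logging.getLogger("clsm")

ANALYSIS_KINDS = ("region", "structural", "functional")


@dataclass(frozen=True)
class AnalysisSpec:
    """One analysis entry of a run config."""

    name: str
    kind: str  # region | structural | functional
    behavior: str = "avc"
    covariate_mode: str = "LESION_VOLUME"
    n_perm: int = 5000
    alpha: float = 0.05
    sidedness: str = "two_sided"
    scheme: str = "freedman_lane"
    min_damage_subjects: int = 10
    critical_rois: tuple[str, ...] = ()
    fisher_z: bool = False
    log1p_fibers: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ANALYSIS_KINDS:
            raise ValueError(f"analysis kind must be one of {ANALYSIS_KINDS}")


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration."""

    seed: int
    output_dir: Path
    cohort_source: str  # "synthetic" or a directory path
    cohort_config: Optional[CohortConfig] = None
    analyses: tuple[AnalysisSpec, ...] = ()
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.cohort_source == "synthetic":
            if self.cohort_config is None:
                raise ValueError("synthetic runs require cohort parameters and a seed")
        elif not Path(self.cohort_source).is_dir():
            raise ValueError(f"cohort directory {self.cohort_source!r} does not exist")


@dataclass(frozen=True)
class RunManifest:
    """Provenance record of one pipeline run."""

    config: dict
    seed: int
    version: str
    outputs: dict  # file -> sha256
    survivor_counts: dict  # analysis name -> count
    fwe_thresholds: dict  # analysis name -> z threshold
    started: str
    finished: str

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True, default=str)


def _tuplify_edges(edges: Any) -> tuple:
    return tuple((int(i), int(j), float(b)) for i, j, b in (edges or ()))


def load_run_config(path: Union[str, Path]) -> RunConfig:
    """Parse a YAML/JSON run config file."""
    raw = yaml.safe_load(Path(path).read_text())
    return parse_run_config(raw, base_dir=Path(path).parent)


def parse_run_config(raw: dict, base_dir: Union[str, Path] = ".") -> RunConfig:
    base = Path(base_dir)
    cohort = dict(raw.get("cohort", {"source": "synthetic"}))
    source = cohort.pop("source", "synthetic")
    cohort_config = None
    if source == "synthetic":
        cohort["planted_fc_edges"] = _tuplify_edges(cohort.get("planted_fc_edges"))
        cohort["planted_sc_edges"] = _tuplify_edges(cohort.get("planted_sc_edges"))
        cohort_config = CohortConfig(**cohort)
    else:
        source = str(base / source) if not Path(source).is_absolute() else source
    analyses = []
    for k, a in enumerate(raw.get("analyses", [])):
        a = dict(a)
        a.setdefault("name", f"analysis-{k}")
        a["critical_rois"] = tuple(a.get("critical_rois", ()))
        analyses.append(AnalysisSpec(**a))
    names = [a.name for a in analyses]
    if len(set(names)) != len(names):
        raise ValueError("analysis names must be unique")
    out_dir = Path(raw.get("output_dir", "clsm-out"))
    if not out_dir.is_absolute():
        out_dir = base / out_dir
    return RunConfig(
        seed=int(raw["seed"]),
        output_dir=out_dir,
        cohort_source=source,
        cohort_config=cohort_config,
        analyses=tuple(analyses),
        log_level=str(raw.get("log_level", "INFO")),
    )


def _load_or_generate(config: RunConfig) -> CohortDataset:
    if config.cohort_source == "synthetic":
        log.info("generating synthetic cohort (n=%d, seed=%d)",
                 config.cohort_config.n_subjects, config.seed)
        return generate_cohort(config.cohort_config, config.seed)
    log.info("loading cohort from %s", config.cohort_source)
    return load_cohort(config.cohort_source)


def _run_one(cohort: CohortDataset, spec: AnalysisSpec, master_seed: int):
    perm = PermutationConfig(
        n_perm=spec.n_perm,
        alpha=spec.alpha,
        seed=master_seed,
        sidedness=spec.sidedness,
        scheme=spec.scheme,
    )
    log.info(
        "analysis %s: kind=%s behavior=%s mode=%s scheme=%s n_perm=%d",
        spec.name, spec.kind, spec.behavior, spec.covariate_mode, spec.scheme, spec.n_perm,
    )
    if spec.kind == "region":
        result = region_lsm(
            cohort, spec.behavior, perm, min_damage_subjects=spec.min_damage_subjects
        )
        return result, None
    if spec.kind == "structural":
        return structural_edge_analysis(
            cohort, spec.behavior, perm, log1p_fibers=spec.log1p_fibers
        )
    cfg = AnalysisConfig(
        behavior=spec.behavior,
        covariate_mode=CovariateMode(spec.covariate_mode),
        permutation=perm,
        critical_rois=spec.critical_rois,
        fisher_z=spec.fisher_z,
        log1p_fibers=spec.log1p_fibers,
    )
    return functional_edge_analysis(cohort, cfg)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute every configured analysis and write results + manifest."""
    logging.basicConfig(level=config.log_level)
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort = _load_or_generate(config)
    outputs: dict[str, str] = {}
    survivor_counts: dict[str, int] = {}
    fwe_thresholds: dict[str, float] = {}
    for spec in config.analyses:
        try:
            result, findings = _run_one(cohort, spec, config.seed)
        except Exception as exc:
            raise RuntimeError(f"analysis {spec.name!r} failed: {exc}") from exc
        zpath = out / f"{spec.name}_z.csv"
        result.save(zpath)
        outputs[zpath.name] = file_sha256(zpath)
        outputs[zpath.with_suffix(".json").name] = file_sha256(zpath.with_suffix(".json"))
        if findings is not None:
            spath = out / f"{spec.name}_survivors.csv"
            with open(spath, "w") as fh:
                fh.write("roi_a,roi_b,z,mode\n")
                for e in findings:
                    fh.write(f"{e.roi_a},{e.roi_b},{e.z!r},{spec.covariate_mode}\n")
            outputs[spath.name] = file_sha256(spath)
        survivor_counts[spec.name] = result.n_survivors
        fwe_thresholds[spec.name] = float(result.fwe_threshold)
        log.info("analysis %s: %d survivor(s), |z| threshold %.3f",
                 spec.name, result.n_survivors, result.fwe_threshold)

    manifest = RunManifest(
        config=_config_dict(config),
        seed=config.seed,
        version=clsm.__version__,
        outputs=outputs,
        survivor_counts=survivor_counts,
        fwe_thresholds=fwe_thresholds,
        started=started,
        finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["output_dir"] = str(d["output_dir"])
    return d
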