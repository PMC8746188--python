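"""Synthetic stroke-cohort generator and behavioral composite scoring.

The generator produces cohorts with the statistical structure the downstream
analyses assume: left-lateralized lesions over a dual-stream parcellation,
fiber counts multiplicatively suppressed by endpoint lesion load, ROI time
courses whose pairwise Pearson correlation tracks the structural backbone,
and behavioral scores linearly driven by a planted set of connectome edges
plus total lesion volume and Gaussian noise.

Generative model
----------------
* Lesion: each left-hemisphere ROI is independently damaged with probability
  ``lesion_damage_prob``; damaged fractions are Beta-distributed. Right
  hemisphere lesion load is identically zero.
* Structural connectome: per-edge lognormal baseline (edge-level log-means
  shared across the cohort, per-subject log-normal jitter) multiplied by
  ``(1 - load_i) * (1 - load_j)`` and rounded to integer streamline counts.
* Time courses: multivariate normal draws whose target correlation on edge
  (i, j) is ``fc_sc_coupling * tanh(fibers_ij / fiber_ref)``, with extra
  per-subject coherence added on planted functional edges; the target matrix
  is projected to the nearest valid correlation matrix before sampling.
* Behavior: a latent comprehension score (points out of 200) equal to
  baseline − lesion_behavior_coef × total lesion volume + Σ β · edge value
  + Gaussian noise, truncated to the legal range and split into integer
  subtest scores whose composites follow the published formulas.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from clsm.parcellation import ParcellationSpec, make_parcellation

__all__ = [
    "interquartile_range",
    "BehaviorScores",
    "CohortConfig",
    "CohortDataset",
    "GroundTruth",
    "SubjectRecord",
    "avc_score",
    "spontaneous_speech_score",
    "simulate_subject",
    "generate_cohort",
    "save_cohort",
    "load_cohort",
]

SeedLike = Union[int, Sequence[int]]


# ---------------------------------------------------------------------------
# Behavioral composite scoring
# ---------------------------------------------------------------------------

def _check_range(name: str, value: float, lo: float, hi: float) -> None:
    if not (lo <= value <= hi):
        raise ValueError(f"{name} must be in [{lo}, {hi}], got {value}")


def interquartile_range(q1: float, q3: float) -> float:
    """Cohort-descriptor arithmetic: IQR from the first and third quartiles."""
    if q3 < q1:
        raise ValueError("third quartile must be >= first quartile")
    return q3 - q1


def avc_score(yes_no: float, word_recognition: float, seq_commands: float) -> float:
    """Auditory Verbal Comprehension composite on the 0-10 weighted scale.

    The three comprehension subtests total 200 points (60 + 60 + 80); the
    composite is that total divided by 20.
    """
    _check_range("yes_no", yes_no, 0, 60)
    _check_range("word_recognition", word_recognition, 0, 60)
    _check_range("seq_commands", seq_commands, 0, 80)
    return (yes_no + word_recognition + seq_commands) / 20


def spontaneous_speech_score(info_content: float, fluency: float) -> float:
    """Spontaneous Speech composite (0-20): information content + fluency."""
    _check_range("info_content", info_content, 0, 10)
    _check_range("fluency", fluency, 0, 10)
    return info_content + fluency


@dataclass(frozen=True)
class BehaviorScores:
    """WAB-R subtest scores and their composites."""

    yes_no: float
    word_recognition: float
    sequential_commands: float
    info_content: float
    fluency: float

    def __post_init__(self) -> None:
        # composite range checks happen in the scoring functions
        avc_score(self.yes_no, self.word_recognition, self.sequential_commands)
        spontaneous_speech_score(self.info_content, self.fluency)

    @property
    def avc(self) -> float:
        return avc_score(self.yes_no, self.word_recognition, self.sequential_commands)

    @property
    def spontaneous_speech(self) -> float:
        return spontaneous_speech_score(self.info_content, self.fluency)


# ---------------------------------------------------------------------------
# Cohort domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroundTruth:
    """Planted effects of a synthetic cohort, for parameter-recovery tests.

    ``planted_fc_edges`` / ``planted_sc_edges`` hold (roi_i, roi_j, beta)
    triples with i < j; beta is in latent behavioral points per unit of edge
    value (Pearson r for functional edges, streamline count for structural).
    """

    planted_fc_edges: tuple[tuple[int, int, float], ...] = ()
    planted_sc_edges: tuple[tuple[int, int, float], ...] = ()
    lesion_behavior_coef: float = 0.0
    noise_sd: float = 1.0
    fc_sc_coupling: float = 0.0

    def __post_init__(self) -> None:
        for i, j, _ in (*self.planted_fc_edges, *self.planted_sc_edges):
            if not (0 <= i < j):
                raise ValueError(f"planted edge ({i}, {j}) must satisfy 0 <= i < j")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not (0.0 <= self.fc_sc_coupling <= 1.0):
            raise ValueError("fc_sc_coupling must be in [0, 1]")


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's lesion data, connectomes, time courses and behavior."""

    lesion_load: np.ndarray          # per-ROI damaged fraction in [0, 1]
    total_lesion_volume: float       # mm^3
    structural: np.ndarray           # symmetric fiber-count matrix, zero diag
    roi_timecourses: np.ndarray      # ROI x time
    behavior: BehaviorScores
    tr: float = 1.65                 # seconds per time sample
    lesion_mask: Optional[np.ndarray] = None  # optional 3-D boolean grid

    def __post_init__(self) -> None:
        s = self.structural
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise ValueError("structural matrix must be square")
        if not np.allclose(s, s.T):
            raise ValueError("structural matrix must be symmetric")
        if np.any(s < 0) or np.any(np.diag(s) != 0):
            raise ValueError("structural matrix must be non-negative with zero diagonal")
        if self.lesion_load.shape != (s.shape[0],):
            raise ValueError("lesion_load length must match parcellation dimension")
        if np.any(self.lesion_load < 0) or np.any(self.lesion_load > 1):
            raise ValueError("lesion_load entries must lie in [0, 1]")


@dataclass(frozen=True)
class CohortConfig:
    """Simulation parameters for :func:`generate_cohort`."""

    n_subjects: int = 97
    n_dorsal_left: int = 26
    n_ventral_per_hemi: int = 41
    n_timepoints: int = 180
    tr: float = 1.65
    roi_volume_mm3: float = 1000.0
    # lesion model
    lesion_damage_prob: float = 0.35
    lesion_beta_a: float = 1.2
    lesion_beta_b: float = 2.5
    # structural model
    fiber_log_mean: float = 4.0
    fiber_log_sd_edges: float = 1.0       # cohort-level edge heterogeneity
    fiber_log_sd_subjects: float = 0.35   # per-subject jitter
    structure_seed: int = 0               # seeds the cohort-shared edge log-means
    # functional coupling
    fc_sc_coupling: float = 0.4
    planted_fc_coherence: float = 0.35    # mean extra coherence on planted FC edges
    planted_fc_coherence_sd: float = 0.18
    # behavior model (latent comprehension scale: points out of 200)
    avc_baseline: float = 175.0
    ss_baseline: float = 17.5             # latent production scale: points out of 20
    lesion_behavior_coef: float = 0.0
    noise_sd: float = 8.0
    planted_fc_edges: tuple[tuple[int, int, float], ...] = ()
    planted_sc_edges: tuple[tuple[int, int, float], ...] = ()

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.n_timepoints < 3:
            raise ValueError("n_timepoints must be >= 3")
        if self.tr <= 0:
            raise ValueError("tr must be > 0")

    def ground_truth(self) -> GroundTruth:
        return GroundTruth(
            planted_fc_edges=tuple(tuple(e) for e in self.planted_fc_edges),
            planted_sc_edges=tuple(tuple(e) for e in self.planted_sc_edges),
            lesion_behavior_coef=self.lesion_behavior_coef,
            noise_sd=self.noise_sd,
            fc_sc_coupling=self.fc_sc_coupling,
        )


@dataclass(frozen=True)
class CohortDataset:
    """A parcellation plus an ordered collection of subjects."""

    parcellation: ParcellationSpec
    subjects: tuple[SubjectRecord, ...]
    seed: int
    ground_truth: Optional[GroundTruth] = None
    config: Optional[CohortConfig] = None

    def __post_init__(self) -> None:
        n = self.parcellation.n_rois
        for k, s in enumerate(self.subjects):
            if s.structural.shape != (n, n):
                raise ValueError(f"subject {k} connectome does not match parcellation")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def behavior_vector(self, which: str) -> np.ndarray:
        """Across-subject vector of a composite score ('avc' or 'spontaneous_speech')."""
        if which not in ("avc", "spontaneous_speech"):
            raise ValueError(f"unknown behavior {which!r}")
        return np.array([getattr(s.behavior, which) for s in self.subjects], float)

    @property
    def total_lesion_volumes(self) -> np.ndarray:
        return np.array([s.total_lesion_volume for s in self.subjects], float)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _edge_log_means(n_rois: int, cfg: CohortConfig) -> np.ndarray:
    """Cohort-shared symmetric matrix of baseline log fiber counts."""
    # fixed salt keeps the cohort-level edge structure independent of subject seeds
    rng = np.random.default_rng((0x5CED6E, cfg.structure_seed))
    mu = cfg.fiber_log_mean + cfg.fiber_log_sd_edges * rng.standard_normal((n_rois, n_rois))
    mu = np.triu(mu, 1)
    return mu + mu.T


def _nearest_correlation(c: np.ndarray, floor: float = 1e-4) -> np.ndarray:
    """Clip eigenvalues and renormalize the diagonal to obtain a valid
    correlation matrix close to ``c``."""
    w, v = np.linalg.eigh(c)
    w = np.maximum(w, floor)
    c2 = (v * w) @ v.T
    d = np.sqrt(np.diag(c2))
    c2 = c2 / np.outer(d, d)
    np.fill_diagonal(c2, 1.0)
    return c2


def _split_subtests(latent: float, maxima: Sequence[float], total: float) -> list[int]:
    """Split a latent total proportionally into integer subtest scores."""
    frac = np.clip(latent / total, 0.0, 1.0)
    return [int(np.clip(round(frac * m), 0, m)) for m in maxima]


def simulate_subject(
    parcellation: ParcellationSpec,
    truth: GroundTruth,
    sim_params: CohortConfig,
    seed: SeedLike,
) -> SubjectRecord:
    """Draw one subject from the generative model (deterministic in ``seed``)."""
    cfg = sim_params
    rng = np.random.default_rng(seed)
    n = parcellation.n_rois

    # --- lesion: left hemisphere only
    load = np.zeros(n)
    left = parcellation.left_ids
    damaged = rng.random(len(left)) < cfg.lesion_damage_prob
    frac = rng.beta(cfg.lesion_beta_a, cfg.lesion_beta_b, size=len(left))
    load[left] = np.where(damaged, frac, 0.0)
    total_volume = float(np.sum(load) * cfg.roi_volume_mm3)

    # --- structural connectome
    mu = _edge_log_means(n, cfg)
    eps = cfg.fiber_log_sd_subjects * rng.standard_normal((n, n))
    eps = np.triu(eps, 1)
    eps = eps + eps.T
    fibers = np.exp(mu + eps)
    suppress = np.outer(1.0 - load, 1.0 - load)
    fibers = np.round(fibers * suppress)
    np.fill_diagonal(fibers, 0.0)

    # --- ROI time courses with SC-coupled target correlation
    fiber_ref = float(np.exp(cfg.fiber_log_mean + cfg.fiber_log_sd_edges**2 / 2))
    target = truth.fc_sc_coupling * np.tanh(fibers / fiber_ref)
    for i, j, _ in truth.planted_fc_edges:
        u = rng.normal(cfg.planted_fc_coherence, cfg.planted_fc_coherence_sd)
        u = float(np.clip(u, 0.0, 0.95 - target[i, j]))
        target[i, j] += u
        target[j, i] += u
    np.fill_diagonal(target, 1.0)
    corr = _nearest_correlation(target)
    chol = np.linalg.cholesky(corr)
    ts = chol @ rng.standard_normal((n, cfg.n_timepoints))

    # --- behavior
    r = np.corrcoef(ts)
    latent = cfg.avc_baseline - truth.lesion_behavior_coef * total_volume
    for i, j, beta in truth.planted_fc_edges:
        latent += beta * r[i, j]
    for i, j, beta in truth.planted_sc_edges:
        latent += beta * fibers[i, j]
    latent += rng.normal(0.0, truth.noise_sd)
    yes_no, word_rec, seq = _split_subtests(latent, (60, 60, 80), 200.0)

    latent_ss = cfg.ss_baseline - truth.lesion_behavior_coef * total_volume * (20.0 / 200.0)
    latent_ss += rng.normal(0.0, truth.noise_sd * 20.0 / 200.0)
    info, fluency = _split_subtests(latent_ss, (10, 10), 20.0)

    behavior = BehaviorScores(
        yes_no=yes_no,
        word_recognition=word_rec,
        sequential_commands=seq,
        info_content=info,
        fluency=fluency,
    )
    return SubjectRecord(
        lesion_load=load,
        total_lesion_volume=total_volume,
        structural=fibers,
        roi_timecourses=ts,
        behavior=behavior,
        tr=cfg.tr,
    )


def generate_cohort(config: CohortConfig, seed: int) -> CohortDataset:
    """Generate ``config.n_subjects`` independent subjects.

    Per-subject seeds are derived deterministically from the master seed and
    the subject index, so regeneration is bit-identical and independent of
    generation order.
    """
    parcellation = make_parcellation(config.n_dorsal_left, config.n_ventral_per_hemi)
    truth = config.ground_truth()
    subjects = tuple(
        simulate_subject(parcellation, truth, config, seed=(seed, k))
        for k in range(config.n_subjects)
    )
    return CohortDataset(
        parcellation=parcellation,
        subjects=subjects,
        seed=seed,
        ground_truth=truth,
        config=config,
    )


# ---------------------------------------------------------------------------
# Serialization (plain-text cohort directory)
# ---------------------------------------------------------------------------

_BEHAVIOR_COLS = [
    "yes_no",
    "word_recognition",
    "sequential_commands",
    "avc",
    "info_content",
    "fluency",
    "spontaneous_speech",
]


def save_cohort(cohort: CohortDataset, out_dir: Union[str, Path]) -> Path:
    """Write a cohort to a directory of plain-text files.

    Layout: ``parcellation.csv``, ``behavior.csv`` (one row per subject,
    subtests, composites and total lesion volume), ``lesion_loads.csv``,
    per-subject labeled structural matrices under ``sc/`` and ROI time
    courses under ``ts/``, and a JSON sidecar with config, seed and ground
    truth.
    """
    from clsm.io import write_connectome_csv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = cohort.parcellation

    pd.DataFrame(
        {
            "roi_id": [r.roi_id for r in p],
            "name": [r.name for r in p],
            "hemisphere": [r.hemisphere for r in p],
            "stream": [r.stream for r in p],
            "subregion": [r.subregion for r in p],
        }
    ).to_csv(out / "parcellation.csv", index=False)

    rows = []
    for k, s in enumerate(cohort.subjects):
        b = s.behavior
        rows.append(
            {
                "subject": f"sub-{k:03d}",
                "yes_no": float(b.yes_no),
                "word_recognition": float(b.word_recognition),
                "sequential_commands": float(b.sequential_commands),
                "avc": float(b.avc),
                "info_content": float(b.info_content),
                "fluency": float(b.fluency),
                "spontaneous_speech": float(b.spontaneous_speech),
                "total_lesion_volume_mm3": repr(s.total_lesion_volume),
            }
        )
    pd.DataFrame(rows).to_csv(out / "behavior.csv", index=False)

    loads = pd.DataFrame(
        np.stack([s.lesion_load for s in cohort.subjects]),
        columns=p.names,
        index=[f"sub-{k:03d}" for k in range(cohort.n_subjects)],
    )
    loads.to_csv(out / "lesion_loads.csv", index_label="subject", float_format="%.17g")

    (out / "sc").mkdir(exist_ok=True)
    (out / "ts").mkdir(exist_ok=True)
    for k, s in enumerate(cohort.subjects):
        write_connectome_csv(out / "sc" / f"sub-{k:03d}.csv", s.structural, p.names)
        ts = pd.DataFrame(
            s.roi_timecourses,
            index=p.names,
            columns=[str(t) for t in range(s.roi_timecourses.shape[1])],
        )
        ts.to_csv(out / "ts" / f"sub-{k:03d}.tsv", sep="\t", index_label="roi", float_format="%.17g")

    sidecar: dict = {"seed": cohort.seed, "tr": cohort.subjects[0].tr}
    if cohort.config is not None:
        sidecar["config"] = dataclasses.asdict(cohort.config)
    if cohort.ground_truth is not None:
        sidecar["ground_truth"] = dataclasses.asdict(cohort.ground_truth)
    (out / "cohort.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return out


def _tuplify_edges(edges) -> tuple[tuple[int, int, float], ...]:
    return tuple((int(i), int(j), float(b)) for i, j, b in edges)


def load_cohort(in_dir: Union[str, Path]) -> CohortDataset:
    """Read a cohort directory written by :func:`save_cohort`."""
    from clsm.io import read_connectome_csv
    from clsm.parcellation import ROI

    src = Path(in_dir)
    pt = pd.read_csv(src / "parcellation.csv")
    rois = tuple(
        ROI(
            int(row.roi_id),
            str(row.name_),
            str(row.hemisphere),
            str(row.stream),
            None if pd.isna(row.subregion) else int(row.subregion),
        )
        for row in pt.rename(columns={"name": "name_"}).itertuples(index=False)
    )
    parcellation = ParcellationSpec(rois)

    sidecar = json.loads((src / "cohort.json").read_text())
    config = None
    truth = None
    if "config" in sidecar:
        c = dict(sidecar["config"])
        c["planted_fc_edges"] = _tuplify_edges(c.get("planted_fc_edges", ()))
        c["planted_sc_edges"] = _tuplify_edges(c.get("planted_sc_edges", ()))
        config = CohortConfig(**c)
    if "ground_truth" in sidecar:
        g = dict(sidecar["ground_truth"])
        g["planted_fc_edges"] = _tuplify_edges(g.get("planted_fc_edges", ()))
        g["planted_sc_edges"] = _tuplify_edges(g.get("planted_sc_edges", ()))
        truth = GroundTruth(**g)

    behavior = pd.read_csv(src / "behavior.csv", float_precision="round_trip")
    loads = pd.read_csv(src / "lesion_loads.csv", index_col="subject", float_precision="round_trip")
    if list(loads.columns) != parcellation.names:
        raise ValueError("lesion_loads.csv columns do not match parcellation")

    tr = float(sidecar.get("tr", 1.65))
    subjects = []
    for row in behavior.itertuples(index=False):
        sid = row.subject
        sc, labels = read_connectome_csv(src / "sc" / f"{sid}.csv")
        if labels != parcellation.names:
            raise ValueError(f"{sid}: structural matrix labels do not match parcellation")
        ts = pd.read_csv(src / "ts" / f"{sid}.tsv", sep="\t", index_col="roi", float_precision="round_trip")
        if list(ts.index) != parcellation.names:
            raise ValueError(f"{sid}: time-course rows do not match parcellation")
        subjects.append(
            SubjectRecord(
                lesion_load=loads.loc[sid].to_numpy(float),
                total_lesion_volume=float(row.total_lesion_volume_mm3),
                structural=sc,
                roi_timecourses=ts.to_numpy(float),
                behavior=BehaviorScores(
                    yes_no=float(row.yes_no),
                    word_recognition=float(row.word_recognition),
                    sequential_commands=float(row.sequential_commands),
                    info_content=float(row.info_content),
                    fluency=float(row.fluency),
                ),
                tr=tr,
            )
        )
    return CohortDataset(
        parcellation=parcellation,
        subjects=tuple(subjects),
        seed=int(sidecar["seed"]),
        ground_truth=truth,
        config=config,
    )
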