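"""Lesion-symptom, structural-edge and resting-state connectivity analyses.

Three families over a cohort:

* region-based lesion-symptom mapping (per-ROI lesion load, total lesion
  volume as covariate, >= 10-subject damage inclusion rule);
* structural connectome edge analysis (per-edge fiber counts, all possible
  connections included, total lesion volume as covariate);
* functional connectome edge analyses in three covariate configurations:
  (a) total lesion volume as a GLM covariate, (b) lesion volume regressed
  out of behavior and each edge's fiber count regressed out of the same
  edge's functional connectivity, (c) as (b) but residualizing behavior on
  the summed lesion load to a set of "critical" ROIs instead of total
  volume.

All families share the permutation max-statistic FWE machinery in
:mod:`clsm.glm`.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from clsm.cohort import CohortDataset, SubjectRecord
from clsm.glm import GLMResult, PermutationConfig, permutation_fwe, residualize
from clsm.parcellation import ParcellationSpec
from clsm.preprocess import functional_connectome

__all__ = [
    "EdgeIndexMap",
    "CovariateMode",
    "AnalysisConfig",
    "EdgeFinding",
    "edge_vectorize",
    "region_lsm",
    "structural_edge_analysis",
    "sc_residualize_fc",
    "critical_area_lesion_load",
    "functional_edge_analysis",
]


class CovariateMode(str, enum.Enum):
    LESION_VOLUME = "LESION_VOLUME"
    LESION_VOLUME_PLUS_SC = "LESION_VOLUME_PLUS_SC"
    CRITICAL_AREAS_PLUS_SC = "CRITICAL_AREAS_PLUS_SC"


@dataclass(frozen=True)
class EdgeIndexMap:
    """Bijection between upper-triangle ROI pairs (i < j) and vector slots."""

    n_rois: int

    def __post_init__(self) -> None:
        if self.n_rois < 2:
            raise ValueError("need at least 2 ROIs to form edges")

    @property
    def n_edges(self) -> int:
        return self.n_rois * (self.n_rois - 1) // 2

    @property
    def pairs(self) -> list[tuple[int, int]]:
        iu = np.triu_indices(self.n_rois, k=1)
        return list(zip(iu[0].tolist(), iu[1].tolist()))

    def position(self, i: int, j: int) -> int:
        """Vector slot of the edge (i, j); order-insensitive, i != j."""
        if i == j:
            raise ValueError("diagonal entries are not edges")
        if i > j:
            i, j = j, i
        if not (0 <= i < j < self.n_rois):
            raise ValueError(f"edge ({i}, {j}) outside parcellation of {self.n_rois} ROIs")
        # slots preceding row i, plus offset within row i
        return i * self.n_rois - i * (i + 1) // 2 + (j - i - 1)

    def vectorize(self, matrix: np.ndarray, atol: float = 1e-8) -> np.ndarray:
        return edge_vectorize(matrix, self, atol=atol)

    def devectorize(self, vec: np.ndarray, diag: float = 0.0) -> np.ndarray:
        """Inverse of :func:`edge_vectorize`; fills the diagonal with ``diag``."""
        vec = np.asarray(vec, float)
        if vec.shape != (self.n_edges,):
            raise ValueError(f"expected {self.n_edges} edge values, got {vec.shape}")
        out = np.zeros((self.n_rois, self.n_rois))
        iu = np.triu_indices(self.n_rois, k=1)
        out[iu] = vec
        out = out + out.T
        np.fill_diagonal(out, diag)
        return out


def edge_vectorize(matrix: np.ndarray, emap: EdgeIndexMap, atol: float = 1e-8) -> np.ndarray:
    """Upper-triangle values of a symmetric matrix in edge-map order."""
    matrix = np.asarray(matrix, float)
    if matrix.shape != (emap.n_rois, emap.n_rois):
        raise ValueError(f"matrix shape {matrix.shape} does not match {emap.n_rois} ROIs")
    if not np.allclose(matrix, matrix.T, atol=atol, equal_nan=True):
        raise ValueError("matrix is not symmetric within tolerance")
    iu = np.triu_indices(emap.n_rois, k=1)
    return matrix[iu]


@dataclass(frozen=True)
class EdgeFinding:
    """One surviving (or reported) edge with its association strength."""

    roi_a: str
    roi_b: str
    z: float
    survived: bool

    def __post_init__(self) -> None:
        if self.roi_a == self.roi_b:
            raise ValueError("an edge must join two distinct ROIs")


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of one functional-connectivity analysis."""

    behavior: str = "avc"  # or "spontaneous_speech"
    covariate_mode: CovariateMode = CovariateMode.LESION_VOLUME
    permutation: PermutationConfig = field(default_factory=PermutationConfig)
    min_damage_subjects: int = 10  # region LSM only
    critical_rois: tuple[str, ...] = ()
    fisher_z: bool = False         # Fisher-transform FC features
    log1p_fibers: bool = False     # log1p-transform fiber counts
    # None = per-mode default (mode a: covariate in the GLM; b/c: pre-residualized)
    covariate_as_regressor: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.behavior not in ("avc", "spontaneous_speech"):
            raise ValueError(f"unknown behavior {self.behavior!r}")
        mode = CovariateMode(self.covariate_mode)
        object.__setattr__(self, "covariate_mode", mode)
        if mode is CovariateMode.CRITICAL_AREAS_PLUS_SC and not self.critical_rois:
            raise ValueError("critical_rois must be non-empty in CRITICAL_AREAS_PLUS_SC mode")


# ---------------------------------------------------------------------------
# Feature assembly helpers
# ---------------------------------------------------------------------------

def _edge_ids(parcellation: ParcellationSpec, emap: EdgeIndexMap) -> list[str]:
    names = parcellation.names
    return [f"{names[i]}--{names[j]}" for i, j in emap.pairs]


def _structural_edges(cohort: CohortDataset, emap: EdgeIndexMap, log1p: bool) -> np.ndarray:
    rows = []
    for k, s in enumerate(cohort.subjects):
        if s.structural is None:
            raise ValueError(f"subject sub-{k:03d} has no structural connectome")
        rows.append(emap.vectorize(s.structural))
    sc = np.stack(rows)
    return np.log1p(sc) if log1p else sc


def _functional_edges(cohort: CohortDataset, emap: EdgeIndexMap, fisher_z: bool) -> np.ndarray:
    rows = []
    for s in cohort.subjects:
        fc = functional_connectome(s.roi_timecourses)
        rows.append(emap.vectorize(fc.r))
    fc_edges = np.stack(rows)
    if fisher_z:
        fc_edges = np.arctanh(np.clip(fc_edges, -1 + 1e-12, 1 - 1e-12))
    return fc_edges


def _survivor_findings(
    result: GLMResult, parcellation: ParcellationSpec, emap: EdgeIndexMap
) -> list[EdgeFinding]:
    """Surviving edges sorted by |z| descending, ties by (roi_a, roi_b)."""
    names = parcellation.names
    found = [
        EdgeFinding(names[i], names[j], float(result.z[k]), True)
        for k, (i, j) in enumerate(emap.pairs)
        if result.survivors[k]
    ]
    found.sort(key=lambda e: (-abs(e.z), e.roi_a, e.roi_b))
    return found


# ---------------------------------------------------------------------------
# Analyses
# ---------------------------------------------------------------------------

def region_lsm(
    cohort: CohortDataset,
    behavior: str = "avc",
    permutation: PermutationConfig = PermutationConfig(),
    min_damage_subjects: int = 10,
    damage_threshold: float = 0.0,
) -> GLMResult:
    """Region-based lesion-symptom mapping.

    Features are per-ROI lesion loads with total lesion volume as the GLM
    covariate. ROIs damaged (load > ``damage_threshold``) in fewer than
    ``min_damage_subjects`` subjects are excluded before permutation; the
    result is indexed by the included ROIs only.
    """
    loads = np.stack([s.lesion_load for s in cohort.subjects])  # (n, R)
    damaged_counts = (loads > damage_threshold).sum(axis=0)
    included = damaged_counts >= min_damage_subjects
    if not included.any():
        warnings.warn("no ROI passes the minimum-damage inclusion rule", stacklevel=2)
        return permutation_fwe(
            cohort.behavior_vector(behavior),
            np.empty((cohort.n_subjects, 0)),
            cohort.total_lesion_volumes,
            permutation,
            feature_ids=(),
        )
    names = [cohort.parcellation.names[i] for i in np.flatnonzero(included)]
    return permutation_fwe(
        cohort.behavior_vector(behavior),
        loads[:, included],
        cohort.total_lesion_volumes,
        permutation,
        feature_ids=names,
    )


def structural_edge_analysis(
    cohort: CohortDataset,
    behavior: str = "avc",
    permutation: PermutationConfig = PermutationConfig(),
    log1p_fibers: bool = False,
) -> tuple[GLMResult, list[EdgeFinding]]:
    """Edge-wise fiber-count GLM, total lesion volume as covariate.

    All possible connections between nodes are included; zero-variance
    edges are flagged undefined and skipped by the permutation engine.
    """
    emap = EdgeIndexMap(cohort.parcellation.n_rois)
    features = _structural_edges(cohort, emap, log1p_fibers)
    result = permutation_fwe(
        cohort.behavior_vector(behavior),
        features,
        cohort.total_lesion_volumes,
        permutation,
        feature_ids=_edge_ids(cohort.parcellation, emap),
    )
    return result, _survivor_findings(result, cohort.parcellation, emap)


def sc_residualize_fc(fc_edges: np.ndarray, sc_edges: np.ndarray) -> np.ndarray:
    """Residualize each FC edge (across subjects) on the same edge's fiber count.

    Column e of the output holds the residuals of ``fc_edges[:, e]``
    regressed on ``[1, sc_edges[:, e]]``. Constant fiber counts reduce to
    mean-centering.
    """
    fc_edges = np.asarray(fc_edges, float)
    sc_edges = np.asarray(sc_edges, float)
    if fc_edges.shape != sc_edges.shape:
        raise ValueError(
            f"fc_edges shape {fc_edges.shape} does not match sc_edges {sc_edges.shape}"
        )
    fc_c = fc_edges - fc_edges.mean(axis=0)
    sc_c = sc_edges - sc_edges.mean(axis=0)
    ss = (sc_c * sc_c).sum(axis=0)
    slope = np.divide(
        (sc_c * fc_c).sum(axis=0), ss, out=np.zeros_like(ss), where=ss > 0
    )
    return fc_c - slope * sc_c


def critical_area_lesion_load(
    subject: SubjectRecord,
    critical_rois: Sequence[str],
    parcellation: ParcellationSpec,
    roi_volumes: Union[float, Mapping[str, float], np.ndarray],
) -> float:
    """Summed lesion load (mm^3) over the listed critical ROIs.

    ``roi_volumes`` is a scalar volume shared by all ROIs, a per-roi_id
    array, or a mapping from ROI name to mm^3.
    """
    if not critical_rois:
        raise ValueError("critical_rois must be non-empty")
    total = 0.0
    for name in critical_rois:
        try:
            rid = parcellation.index_of(name)
        except KeyError:
            raise ValueError(f"unknown ROI label {name!r}") from None
        if isinstance(roi_volumes, Mapping):
            vol = float(roi_volumes[name])
        elif np.isscalar(roi_volumes):
            vol = float(roi_volumes)
        else:
            vol = float(np.asarray(roi_volumes)[rid])
        total += float(subject.lesion_load[rid]) * vol
    return total


def functional_edge_analysis(
    cohort: CohortDataset, config: AnalysisConfig
) -> tuple[GLMResult, list[EdgeFinding]]:
    """Functional-connectivity edge GLM in one of the three covariate modes.

    Mode LESION_VOLUME: FC edges are the features and total lesion volume
    enters each GLM as a covariate. Mode LESION_VOLUME_PLUS_SC: behavior is
    residualized on total lesion volume, FC edges are residualized on the
    matching structural edges, then a covariate-free edge GLM runs. Mode
    CRITICAL_AREAS_PLUS_SC: as the previous mode but behavior is
    residualized on the summed critical-area lesion load. The per-mode
    covariate handling can be overridden with
    ``config.covariate_as_regressor``.
    """
    emap = EdgeIndexMap(cohort.parcellation.n_rois)
    y = cohort.behavior_vector(config.behavior)
    fc_edges = _functional_edges(cohort, emap, config.fisher_z)
    ids = _edge_ids(cohort.parcellation, emap)
    mode = config.covariate_mode

    if mode is CovariateMode.LESION_VOLUME:
        covariate = cohort.total_lesion_volumes
        features = fc_edges
    else:
        sc_edges = _structural_edges(cohort, emap, config.log1p_fibers)
        features = sc_residualize_fc(fc_edges, sc_edges)
        if mode is CovariateMode.LESION_VOLUME_PLUS_SC:
            covariate = cohort.total_lesion_volumes
        else:
            vol = cohort.config.roi_volume_mm3 if cohort.config is not None else 1.0
            covariate = np.array(
                [
                    critical_area_lesion_load(
                        s, config.critical_rois, cohort.parcellation, vol
                    )
                    for s in cohort.subjects
                ]
            )

    as_regressor = config.covariate_as_regressor
    if as_regressor is None:
        as_regressor = mode is CovariateMode.LESION_VOLUME
    if as_regressor:
        result = permutation_fwe(y, features, covariate, config.permutation, feature_ids=ids)
    else:
        result = permutation_fwe(
            residualize(y, covariate), features, None, config.permutation, feature_ids=ids
        )
    return result, _survivor_findings(result, cohort.parcellation, emap)
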