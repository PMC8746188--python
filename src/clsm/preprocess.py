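"""Resting-state time-course conditioning and connectome construction.

Implements nuisance detrending, 0.01-0.1 Hz band-pass filtering, the
lesion-driven ICA-component filter (Jaccard overlap > 5% between the
thresholded component z-map and the lesion mask), lesion-mask smoothing and
50%-cutoff binarization, ROI time-course averaging, and Pearson functional
connectome computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, signal, stats

__all__ = [
    "VoxelTimeSeries",
    "NuisanceRegressors",
    "ICADecomposition",
    "BinaryMask",
    "FunctionalConnectome",
    "smooth_binarize_mask",
    "detrend_timecourses",
    "bandpass",
    "jaccard",
    "threshold_component_map",
    "lesion_component_filter",
    "roi_mean_timecourses",
    "functional_connectome",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class VoxelTimeSeries:
    """A 4-D voxel time series (x, y, z, t) with TR in seconds."""

    data: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D (x, y, z, t)")
        if self.tr <= 0:
            raise ValueError("tr must be > 0")
        if self.data.shape[-1] < 2:
            raise ValueError("time dimension must be >= 2")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[-1]

    def as_time_major(self) -> np.ndarray:
        """Flattened (time, voxel) view of the data."""
        return self.data.reshape(-1, self.n_timepoints).T


@dataclass(frozen=True)
class BinaryMask:
    """A 3-D boolean voxel mask."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        if self.grid.ndim != 3:
            raise ValueError("mask grid must be 3-D")
        if self.grid.dtype != bool:
            object.__setattr__(self, "grid", self.grid.astype(bool))

    @property
    def volume_voxels(self) -> int:
        return int(self.grid.sum())


@dataclass(frozen=True)
class NuisanceRegressors:
    """Detrending regressors: motion, WM/CSF means and polynomial trends."""

    motion: np.ndarray                 # (T, 6)
    wm_mean: np.ndarray                # (T,)
    csf_mean: np.ndarray               # (T,)
    poly: np.ndarray = field(default=None)  # (T, 3): linear, quadratic, cubic

    def __post_init__(self) -> None:
        t = len(self.wm_mean)
        if self.poly is None:
            object.__setattr__(self, "poly", polynomial_trends(t))
        if self.motion.shape != (t, 6):
            raise ValueError(f"motion must be (T, 6) with T={t}, got {self.motion.shape}")
        if self.csf_mean.shape != (t,) or self.poly.shape != (t, 3):
            raise ValueError("all regressor columns must share the time dimension")

    @property
    def n_timepoints(self) -> int:
        return len(self.wm_mean)

    def design(self) -> np.ndarray:
        """Stacked (T, 11) design: motion | wm | csf | linear, quad, cubic."""
        return np.column_stack([self.motion, self.wm_mean, self.csf_mean, self.poly])


def polynomial_trends(n_timepoints: int) -> np.ndarray:
    """Linear, quadratic and cubic trend columns over a centered time axis."""
    t = np.linspace(-1.0, 1.0, n_timepoints)
    return np.column_stack([t, t**2, t**3])


@dataclass(frozen=True)
class ICADecomposition:
    """Z-scored spatial component maps plus component time courses.

    ``spatial_z`` is (components, x, y, z); ``timecourses`` is
    (components, time). Any ICA backend may supply these; they are treated
    as given.
    """

    spatial_z: np.ndarray
    timecourses: np.ndarray

    def __post_init__(self) -> None:
        if self.spatial_z.ndim != 4:
            raise ValueError("spatial_z must be (components, x, y, z)")
        if self.timecourses.ndim != 2:
            raise ValueError("timecourses must be (components, time)")
        if self.spatial_z.shape[0] != self.timecourses.shape[0]:
            raise ValueError("component counts of spatial_z and timecourses differ")

    @property
    def n_components(self) -> int:
        return self.spatial_z.shape[0]


@dataclass(frozen=True)
class FunctionalConnectome:
    """Symmetric Pearson correlation matrix over ROIs.

    ``undefined`` flags entries involving a zero-variance time course; those
    entries are NaN in ``r`` rather than silently zero.
    """

    r: np.ndarray
    undefined: np.ndarray = None
    labels: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if self.undefined is None:
            object.__setattr__(self, "undefined", np.zeros(self.r.shape, bool))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def smooth_binarize_mask(
    prob_mask: np.ndarray,
    fwhm_mm: float,
    voxel_size_mm: float,
    cutoff: float = 0.5,
) -> BinaryMask:
    """Gaussian-smooth a probabilistic mask and binarize at ``cutoff``.

    Smoothing uses sigma = FWHM / (2 * sqrt(2 ln 2)) per axis; the 50%
    cutoff approximately conserves the volume of large solid regions, so
    lesions are neither dilated nor eroded.
    """
    prob_mask = np.asarray(prob_mask, float)
    if prob_mask.ndim != 3:
        raise ValueError("prob_mask must be 3-D")
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if not (0.0 < cutoff < 1.0):
        raise ValueError("cutoff must lie in (0, 1)")
    if fwhm_mm > 0:
        sigma = fwhm_mm * FWHM_TO_SIGMA / voxel_size_mm
        smoothed = ndimage.gaussian_filter(prob_mask, sigma=sigma)
    else:
        smoothed = prob_mask
    return BinaryMask(smoothed >= cutoff)


def detrend_timecourses(ts: np.ndarray, regressors: NuisanceRegressors) -> np.ndarray:
    """Residualize time-major series against nuisance regressors + intercept.

    ``ts`` is (T,) or (T, V); output residuals are orthogonal to every
    regressor column and to the intercept. Rank-deficient designs are
    handled by least squares.
    """
    ts = np.asarray(ts, float)
    one_d = ts.ndim == 1
    y = ts[:, None] if one_d else ts
    t = y.shape[0]
    if regressors.n_timepoints != t:
        raise ValueError(
            f"regressor length {regressors.n_timepoints} does not match time dimension {t}"
        )
    x = np.column_stack([np.ones(t), regressors.design()])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return resid[:, 0] if one_d else resid


def bandpass(
    ts: np.ndarray,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
    tr: float = 1.65,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the time (first) axis."""
    ts = np.asarray(ts, float)
    nyquist = 0.5 / tr
    if not (0.0 < low_hz < high_hz):
        raise ValueError("must have 0 < low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(f"high_hz={high_hz} must be below the Nyquist frequency {nyquist:.4g}")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=1.0 / tr, output="sos")
    return signal.sosfiltfilt(sos, ts, axis=0)


def jaccard(a: BinaryMask, b: BinaryMask) -> float:
    """Jaccard index |a ∩ b| / |a ∪ b|; 0 when both masks are empty."""
    if a.grid.shape != b.grid.shape:
        raise ValueError(f"mask shapes differ: {a.grid.shape} vs {b.grid.shape}")
    union = np.logical_or(a.grid, b.grid).sum()
    if union == 0:
        return 0.0
    inter = np.logical_and(a.grid, b.grid).sum()
    return float(inter / union)


def threshold_component_map(z_map: np.ndarray, map_alpha: float = 0.05) -> BinaryMask:
    """Two-sided threshold of a z-scored spatial map at p < ``map_alpha``."""
    z_crit = stats.norm.ppf(1.0 - map_alpha / 2.0)
    return BinaryMask(np.abs(np.asarray(z_map, float)) > z_crit)


def lesion_component_filter(
    ts: VoxelTimeSeries,
    ica: ICADecomposition,
    lesion: BinaryMask,
    map_alpha: float = 0.05,
    overlap_threshold: float = 0.05,
) -> tuple[VoxelTimeSeries, list[int]]:
    """Regress lesion-overlapping ICA components out of every voxel series.

    A component is flagged when the Jaccard overlap between its thresholded
    z-map and the lesion mask is strictly greater than ``overlap_threshold``.
    Flagged component time courses are removed by least squares (with
    intercept); non-flagged components are untouched.
    """
    if ica.spatial_z.shape[1:] != ts.grid_shape:
        raise ValueError("ICA spatial maps do not match the voxel grid")
    if ica.timecourses.shape[1] != ts.n_timepoints:
        raise ValueError("ICA time courses do not match the time dimension")
    if lesion.grid.shape != ts.grid_shape:
        raise ValueError("lesion mask does not match the voxel grid")

    removed: list[int] = []
    for c in range(ica.n_components):
        comp_mask = threshold_component_map(ica.spatial_z[c], map_alpha)
        if jaccard(comp_mask, lesion) > overlap_threshold:
            removed.append(c)
    if not removed:
        return ts, []

    y = ts.as_time_major()  # (T, V)
    x = np.column_stack([np.ones(ts.n_timepoints), ica.timecourses[removed].T])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    filtered = resid.T.reshape(ts.data.shape)
    return VoxelTimeSeries(filtered, ts.tr), removed


def roi_mean_timecourses(
    ts: VoxelTimeSeries,
    roi_map: np.ndarray,
    labels: Sequence[int],
    background_label: int = 0,
) -> np.ndarray:
    """Average voxel time courses within each ROI of a labeled parcellation map.

    Returns an (ROI, time) array in the order of ``labels``. ROIs with no
    member voxels are returned as NaN rows (missing, not zero-filled). Map
    labels outside ``labels`` (other than the background label) raise.
    """
    roi_map = np.asarray(roi_map)
    if roi_map.shape != ts.grid_shape:
        raise ValueError("roi_map shape does not match the voxel grid")
    known = set(int(v) for v in labels) | {background_label}
    present = set(int(v) for v in np.unique(roi_map))
    unknown = present - known
    if unknown:
        raise ValueError(f"roi_map contains labels not in the parcellation: {sorted(unknown)}")

    flat_map = roi_map.ravel()
    flat_ts = ts.data.reshape(-1, ts.n_timepoints)
    out = np.full((len(labels), ts.n_timepoints), np.nan)
    for k, lab in enumerate(labels):
        members = flat_map == lab
        if members.any():
            out[k] = flat_ts[members].mean(axis=0)
    return out


def functional_connectome(
    roi_ts: np.ndarray, labels: Optional[Sequence[str]] = None
) -> FunctionalConnectome:
    """Pearson correlation connectome from (ROI, time) mean time courses.

    Zero-variance series produce NaN, undefined-flagged rows/columns and a
    warning; the diagonal is 1 everywhere.
    """
    roi_ts = np.asarray(roi_ts, float)
    if roi_ts.ndim != 2:
        raise ValueError("roi_ts must be 2-D (ROI, time)")
    if roi_ts.shape[1] < 3:
        raise ValueError("need >= 3 time points to correlate")
    sd = roi_ts.std(axis=1)
    degenerate = (sd == 0) | ~np.isfinite(sd) | np.isnan(roi_ts).any(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(roi_ts)
    undefined = np.zeros(r.shape, bool)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} ROI time course(s) have zero variance or missing "
            "data; their correlations are flagged undefined",
            stacklevel=2,
        )
        undefined[degenerate, :] = True
        undefined[:, degenerate] = True
        r[undefined] = np.nan
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(undefined, False)
    lab = tuple(labels) if labels is not None else None
    return FunctionalConnectome(r=r, undefined=undefined, labels=lab)
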