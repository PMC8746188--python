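"""Mass-univariate GLM core with max-statistic permutation FWE control.

Each feature (ROI lesion load, structural edge, functional edge) enters its
own ordinary-least-squares model ``y ~ 1 + feature + covariates``; the
feature coefficient's t-statistic is converted to a signed z-score by the
probability-preserving transform z = Phi^{-1}(F_t(t; dof)). Family-wise
error is controlled with the empirical max-|z| distribution over
permutations of the response (Freedman-Lane when nuisance covariates are
present: the covariate fit is retained and only its residuals are permuted).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PermutationConfig",
    "FeatureStat",
    "GLMResult",
    "residualize",
    "t_to_z",
    "glm_feature_z",
    "permutation_fwe",
]

SIDEDNESS = ("two_sided", "one_sided_pos", "one_sided_neg")


@dataclass(frozen=True)
class PermutationConfig:
    """Permutation-test settings."""

    n_perm: int = 5000
    alpha: float = 0.05
    seed: int = 0
    sidedness: str = "two_sided"
    scheme: str = "freedman_lane"  # or "raw": permute y itself

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.sidedness not in SIDEDNESS:
            raise ValueError(f"sidedness must be one of {SIDEDNESS}")
        if self.scheme not in ("freedman_lane", "raw"):
            raise ValueError("scheme must be 'freedman_lane' or 'raw'")


@dataclass(frozen=True)
class FeatureStat:
    """Per-feature GLM statistics for a single feature."""

    t: float
    z: float
    p: float
    dof: int
    undefined: bool = False


@dataclass(frozen=True)
class GLMResult:
    """Mass-univariate result with the permutation FWE threshold.

    ``survivors[i]`` is True iff feature i exceeds the threshold under the
    configured sidedness (``|z| > fwe_threshold`` when two-sided).
    Undefined (zero-variance) features carry NaN statistics and never
    survive.
    """

    feature_ids: tuple[str, ...]
    z: np.ndarray
    p_uncorrected: np.ndarray
    p_fwe: np.ndarray
    fwe_threshold: float
    survivors: np.ndarray
    undefined: np.ndarray
    dof: int
    n_perm: int
    alpha: float
    seed: int
    sidedness: str
    scheme: str
    warnings: tuple[str, ...] = ()

    @property
    def n_survivors(self) -> int:
        return int(self.survivors.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": list(self.feature_ids),
                "z": self.z,
                "p_uncorrected": self.p_uncorrected,
                "p_fwe": self.p_fwe,
                "survivor": self.survivors,
                "undefined": self.undefined,
            }
        )

    def provenance(self) -> dict:
        return {
            "n_perm": self.n_perm,
            "alpha": self.alpha,
            "seed": self.seed,
            "sidedness": self.sidedness,
            "scheme": self.scheme,
            "dof": self.dof,
            "fwe_threshold": float(self.fwe_threshold),
            "n_survivors": self.n_survivors,
            "warnings": list(self.warnings),
        }

    def save(self, csv_path: Union[str, Path]) -> None:
        """Write the per-feature table plus a JSON provenance sidecar."""
        csv_path = Path(csv_path)
        self.to_frame().to_csv(csv_path, index=False, float_format="%.17g")
        sidecar = csv_path.with_suffix(".json")
        sidecar.write_text(json.dumps(self.provenance(), indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def _as_design(x: Optional[np.ndarray], n: int) -> np.ndarray:
    """Covariates as an (n, k) array; None or empty means k = 0."""
    if x is None:
        return np.empty((n, 0))
    x = np.asarray(x, float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] != n:
        raise ValueError(f"covariate rows ({x.shape[0]}) do not match n ({n})")
    return x


def residualize(y: np.ndarray, X: Optional[np.ndarray] = None) -> np.ndarray:
    """Least-squares residuals of ``y`` on [intercept | X].

    ``y`` may be (n,) or (n, m); columns are residualized independently.
    With no covariates this mean-centers. Collinear designs are handled by
    least squares (pseudoinverse).
    """
    y = np.asarray(y, float)
    one_d = y.ndim == 1
    yy = y[:, None] if one_d else y
    n = yy.shape[0]
    design = np.column_stack([np.ones(n), _as_design(X, n)])
    beta, *_ = np.linalg.lstsq(design, yy, rcond=None)
    resid = yy - design @ beta
    return resid[:, 0] if one_d else resid


def t_to_z(t, dof: int):
    """Probability-preserving conversion of t-statistics to signed z-scores.

    z = Phi^{-1}(F_t(t; dof)); computed through the upper tail for positive
    t (and symmetrically for negative t) so extreme values keep precision.
    """
    if dof < 1:
        raise ValueError("dof must be >= 1")
    t_arr = np.asarray(t, float)
    if not np.all(np.isfinite(t_arr)):
        raise ValueError("t statistics must be finite")
    pos_tail = stats.t.sf(np.abs(t_arr), dof)
    z = stats.norm.isf(pos_tail) * np.sign(t_arr)
    # sign(0) == 0 loses the exact-median case; Phi^-1(1/2) = 0 anyway
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(z)
    return z


def glm_feature_z(
    y: np.ndarray,
    feature: np.ndarray,
    covariates: Optional[np.ndarray] = None,
) -> FeatureStat:
    """OLS of ``y`` on [intercept | feature | covariates]; feature t, z, p.

    dof = n - (2 + #covariates); p is two-sided. A zero-variance feature
    yields an undefined-flagged result (NaN statistics).
    """
    y = np.asarray(y, float)
    feature = np.asarray(feature, float)
    n = y.shape[0]
    if feature.shape != (n,):
        raise ValueError("feature length must match y")
    c = _as_design(covariates, n)
    dof = n - (2 + c.shape[1])
    if dof < 3:
        raise ValueError(f"insufficient degrees of freedom: n={n}, covariates={c.shape[1]}")
    if np.ptp(feature) == 0:
        return FeatureStat(np.nan, np.nan, np.nan, dof, undefined=True)

    x = np.column_stack([np.ones(n), feature, c])
    xtx_inv = np.linalg.pinv(x.T @ x)
    beta = xtx_inv @ (x.T @ y)
    resid = y - x @ beta
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    with np.errstate(divide="ignore"):
        t = float(beta[1] / se) if se > 0 else float(np.copysign(np.inf, beta[1]))
    if not np.isfinite(t):
        # perfect fit: the probability-preserving map sends it to +/- infinity
        return FeatureStat(t=t, z=t, p=0.0, dof=dof, undefined=False)
    z = t_to_z(t, dof)
    p = 2.0 * float(stats.t.sf(abs(t), dof))
    return FeatureStat(t=t, z=z, p=p, dof=dof, undefined=False)


# ---------------------------------------------------------------------------
# Batch machinery (shared by the permutation engine)
# ---------------------------------------------------------------------------

def _batch_partial_t(
    y_resid: np.ndarray, f_resid: np.ndarray, f_norm: np.ndarray, dof: int
) -> np.ndarray:
    """t-statistics of each feature column against each response column.

    ``y_resid`` is (n, P) covariate-residualized responses, ``f_resid`` is
    (n, m) covariate-residualized features with column norms ``f_norm``.
    Equals the OLS feature t by the Frisch-Waugh-Lovell identity.
    Returns (m, P).
    """
    y_norm = np.linalg.norm(y_resid, axis=0)
    y_norm = np.where(y_norm == 0, np.nan, y_norm)
    r = (f_resid.T @ y_resid) / np.outer(f_norm, y_norm)
    r = np.clip(r, -1.0 + 1e-15, 1.0 - 1e-15)
    return r * np.sqrt(dof / (1.0 - r * r))


def permutation_fwe(
    y: np.ndarray,
    features: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    cfg: PermutationConfig = PermutationConfig(),
    feature_ids: Optional[Sequence[str]] = None,
) -> GLMResult:
    """Mass-univariate GLM with max-statistic permutation FWE thresholding.

    Observed z-scores come from :func:`glm_feature_z` applied to every
    column of ``features``; the FWE threshold is the empirical
    ``1 - alpha`` quantile of the max-|z| (two-sided) distribution over
    ``cfg.n_perm`` permutations of the response, with features and
    covariates held fixed. Under the default Freedman-Lane scheme the
    response's covariate fit is retained and only the covariate residuals
    are permuted. Permutation indices are pre-generated from ``cfg.seed``,
    so results are reproducible and independent of execution order.
    """
    y = np.asarray(y, float)
    features = np.asarray(features, float)
    if features.ndim != 2:
        raise ValueError("features must be 2-D (subjects, features)")
    n, m = features.shape
    if y.shape != (n,):
        raise ValueError(f"y length {y.shape} does not match features rows {n}")
    c = _as_design(covariates, n)
    k = c.shape[1]
    dof = n - (2 + k)
    if dof < 3:
        raise ValueError(f"insufficient degrees of freedom: n={n}, covariates={k}")
    if feature_ids is None:
        feature_ids = tuple(f"f{i}" for i in range(m))
    else:
        feature_ids = tuple(str(f) for f in feature_ids)
        if len(feature_ids) != m:
            raise ValueError("feature_ids length does not match features")

    warn_msgs: list[str] = []
    if cfg.n_perm < 1.0 / cfg.alpha:
        msg = (
            f"n_perm={cfg.n_perm} is too small to resolve alpha={cfg.alpha} "
            f"(need >= {int(np.ceil(1 / cfg.alpha))}); threshold computed anyway"
        )
        warnings.warn(msg, stacklevel=2)
        warn_msgs.append(msg)

    nuisance = np.column_stack([np.ones(n), c])
    beta_n, *_ = np.linalg.lstsq(nuisance, features, rcond=None)
    f_resid = features - nuisance @ beta_n
    f_norm = np.linalg.norm(f_resid, axis=0)
    undefined = (np.ptp(features, axis=0) == 0) | (f_norm <= 1e-12 * np.abs(features).max(initial=1.0))
    f_norm_safe = np.where(undefined, np.nan, f_norm)

    beta_y, *_ = np.linalg.lstsq(nuisance, y[:, None], rcond=None)
    y_fit = (nuisance @ beta_y)[:, 0]
    y_resid = y - y_fit

    t_obs = _batch_partial_t(y_resid[:, None], f_resid, f_norm_safe, dof)[:, 0]
    z_obs = np.full(m, np.nan)
    ok = ~undefined
    if ok.any():
        z_obs[ok] = t_to_z(t_obs[ok], dof)
    p_unc = 2.0 * stats.t.sf(np.abs(t_obs), dof)

    # pre-generated permutation indices (reproducible, parallel-safe)
    rng = np.random.default_rng(cfg.seed)
    perms = np.stack([rng.permutation(n) for _ in range(cfg.n_perm)], axis=1)  # (n, P)

    if cfg.scheme == "freedman_lane":
        y_perm = y_fit[:, None] + y_resid[perms]
    else:
        y_perm = y[perms]
    # re-residualize permuted responses on the nuisance design
    beta_p, *_ = np.linalg.lstsq(nuisance, y_perm, rcond=None)
    y_perm_resid = y_perm - nuisance @ beta_p

    t_perm = _batch_partial_t(y_perm_resid, f_resid[:, ok], f_norm_safe[ok], dof)
    if not ok.any():
        t_perm = np.zeros((0, cfg.n_perm))

    if cfg.sidedness == "two_sided":
        stat_obs = np.abs(t_obs)
        stat_max = np.abs(t_perm).max(axis=0) if t_perm.size else np.zeros(cfg.n_perm)
    elif cfg.sidedness == "one_sided_pos":
        stat_obs = t_obs
        stat_max = t_perm.max(axis=0) if t_perm.size else np.zeros(cfg.n_perm)
    else:
        stat_obs = -t_obs
        stat_max = (-t_perm).max(axis=0) if t_perm.size else np.zeros(cfg.n_perm)

    # max-|z| is monotone in max-|t|, so threshold in t-space then convert
    t_threshold = float(np.quantile(stat_max, 1.0 - cfg.alpha, method="higher"))
    z_threshold = abs(t_to_z(t_threshold, dof))
    survivors = np.zeros(m, bool)
    survivors[ok] = stat_obs[ok] > t_threshold

    # corrected p with the (k+1)/(P+1) convention: never exactly 0
    p_fwe = np.full(m, np.nan)
    if ok.any():
        exceed = (stat_max[None, :] >= stat_obs[ok, None]).sum(axis=1)
        p_fwe[ok] = (1.0 + exceed) / (cfg.n_perm + 1.0)

    p_unc = np.where(undefined, np.nan, p_unc)
    return GLMResult(
        feature_ids=feature_ids,
        z=z_obs,
        p_uncorrected=p_unc,
        p_fwe=p_fwe,
        fwe_threshold=z_threshold,
        survivors=survivors,
        undefined=undefined,
        dof=dof,
        n_perm=cfg.n_perm,
        alpha=cfg.alpha,
        seed=cfg.seed,
        sidedness=cfg.sidedness,
        scheme=cfg.scheme,
        warnings=tuple(warn_msgs),
    )
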