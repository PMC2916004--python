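"""MCAR multiple imputation of missing per-arm covariates.

Each missing cell is first filled by a bootstrap draw from the observed
values of its column (one column per covariate/arm pair), after which sweeps
of ordinary least-squares regression — each partially observed column
regressed on all other covariate columns — re-predict the missing cells
until the largest absolute change falls below a tolerance.  Missingness is
assumed completely at random, so the observed-value distribution is an
unbiased donor pool.  Observed cells are never altered.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .data_model import Dataset, _looks_like_proportion

__all__ = ["ImputationConfig", "impute", "mask_mcar"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ImputationConfig:
    n_datasets: int = 3
    max_sweeps: int = 300
    convergence_tol: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if self.n_datasets < 1 or self.max_sweeps < 1 or self.convergence_tol <= 0:
            raise ValueError("imputation config values must be positive")


def _columns(data: Dataset) -> list[tuple[str, str]]:
    return [(name, suffix) for name in data.covariate_names for suffix in ("T", "C")]


def _matrix(data: Dataset) -> np.ndarray:
    """Covariate matrix, rows = studies, cols = (covariate, arm); NaN = missing."""
    cols = _columns(data)
    out = np.full((data.n_studies, len(cols)), np.nan)
    for j, study in enumerate(data.studies):
        for c, (name, suffix) in enumerate(cols):
            arm = study.treatment_arm if suffix == "T" else study.control_arm
            value = arm.covariates.get(name)
            if value is not None and not np.isnan(value):
                out[j, c] = value
    return out


def _rebuild(data: Dataset, matrix: np.ndarray) -> Dataset:
    cols = _columns(data)
    studies = []
    for j, study in enumerate(data.studies):
        arms = {}
        for key, suffix in (("treatment_arm", "T"), ("control_arm", "C")):
            arm = getattr(study, key)
            covs = dict(arm.covariates)
            for c, (name, s) in enumerate(cols):
                if s == suffix:
                    covs[name] = float(matrix[j, c])
            arms[key] = replace(arm, covariates=covs)
        studies.append(replace(study, **arms))
    return Dataset(studies=studies, covariate_names=list(data.covariate_names))


def impute(data: Dataset, config: ImputationConfig | None = None) -> list[Dataset]:
    """Return ``n_datasets`` complete copies of ``data`` with missing cells filled.

    Raises if any covariate column is observed in fewer than two studies.
    """
    config = config or ImputationConfig()
    base = _matrix(data)
    cols = _columns(data)
    missing = np.isnan(base)
    for c, (name, suffix) in enumerate(cols):
        if np.sum(~missing[:, c]) < 2:
            raise ValueError(
                f"covariate {name}_{suffix} observed in fewer than 2 studies; cannot impute"
            )
    if not missing.any():
        return [_rebuild(data, base) for _ in range(config.n_datasets)]

    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed))
    results = []
    for _ in range(config.n_datasets):
        filled = base.copy()
        # 1. bootstrap fill: draw each missing cell from the column's observed values
        for c in range(filled.shape[1]):
            observed = base[~missing[:, c], c]
            n_miss = int(missing[:, c].sum())
            if n_miss:
                filled[missing[:, c], c] = rng.choice(observed, size=n_miss, replace=True)
        # 2. iterative regression sweeps
        converged = False
        for _sweep in range(config.max_sweeps):
            max_change = 0.0
            for c in range(filled.shape[1]):
                rows = missing[:, c]
                if not rows.any():
                    continue
                others = np.delete(filled, c, axis=1)
                X = np.column_stack([np.ones(filled.shape[0]), others])
                coef, *_ = np.linalg.lstsq(X[~rows], base[~rows, c], rcond=None)
                predicted = X[rows] @ coef
                if _looks_like_proportion(cols[c][0]):
                    predicted = np.clip(predicted, 0.0, 1.0)
                max_change = max(max_change, float(np.max(np.abs(predicted - filled[rows, c]))))
                filled[rows, c] = predicted
            if max_change < config.convergence_tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                "iterative regression imputation did not converge within "
                f"{config.max_sweeps} sweeps (last change {max_change:.3g})",
                stacklevel=2,
            )
        results.append(_rebuild(data, filled))
    return results


def mask_mcar(data: Dataset, fraction: float, seed: int = 0) -> Dataset:
    """Set each covariate cell missing independently with probability ``fraction``.

    Counts are untouched.  A test harness for imputation quality on complete
    synthetic data.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    matrix = _matrix(data)
    drop = rng.random(matrix.shape) < fraction
    masked = _rebuild(data, matrix)
    cols = _columns(data)
    for j, study in enumerate(masked.studies):
        for c, (name, suffix) in enumerate(cols):
            if drop[j, c]:
                arm = study.treatment_arm if suffix == "T" else study.control_arm
                arm.covariates[name] = None
    return masked
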