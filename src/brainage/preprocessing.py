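"""Feature preprocessing: TIV normalisation, robust scaling, incremental PCA.

All statistics are estimated on training rows only and re-applied to held-out
rows; every fit records the subject ids it saw (``seen_ids_``) so that
cross-validation can audit that no validation or independent-site row ever
leaked into a fit.

Pipeline order is fixed and deliberate: region volumes are divided by TIV and
then robust-scaled; voxel features go into PCA unscaled and the resulting
component scores are robust-scaled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import IncrementalPCA

from .cohort import Cohort, ParameterError

__all__ = [
    "DataError",
    "RobustScaler",
    "PCAConfig",
    "IncrementalPCABasis",
    "normalise_by_tiv",
]


class DataError(ValueError):
    """Invalid data handed to a preprocessing step."""


def normalise_by_tiv(cohort: Cohort) -> Cohort:
    """Divide every region volume by the subject's total intracranial volume.

    Removes head-size variance from the volumes.  The TIV column is retained
    (marked consumed in provenance) but must not be used as a feature after
    this step.
    """
    if cohort.feature_kind != "region":
        raise DataError("TIV normalisation applies to region-kind cohorts only")
    tiv = cohort.tiv
    bad = np.flatnonzero(tiv <= 0)
    if bad.size:
        raise DataError(
            f"non-positive TIV for subject(s) {', '.join(cohort.ids[bad[:5]])}"
        )
    out = cohort.subset(np.arange(cohort.n_subjects))
    out.features = cohort.features / tiv[:, None]
    out.provenance = dict(cohort.provenance) | {"tiv_normalised": True}
    return out


class RobustScaler:
    """Median / interquartile-range scaling with training-set statistics.

    ``(x - median) / (q75 - q25)`` per feature, quantiles by linear
    interpolation (type-7).  A zero IQR leaves the feature unscaled
    (scale 1) with a warning, so degenerate synthetic features cannot
    crash a cross-validation run.
    """

    def __init__(self) -> None:
        self.center_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None
        self.seen_ids_: np.ndarray | None = None

    @property
    def fitted(self) -> bool:
        return self.center_ is not None

    def fit(self, X: np.ndarray, row_ids: np.ndarray | None = None) -> "RobustScaler":
        X = np.asarray(X, float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise DataError("robust scaler needs a 2-D array with >= 2 rows")
        self.center_ = np.median(X, axis=0)
        q25, q75 = np.percentile(X, [25.0, 75.0], axis=0)
        iqr = q75 - q25
        zero = iqr == 0
        if np.any(zero):
            warnings.warn(
                f"{int(zero.sum())} feature(s) have zero IQR; leaving them unscaled",
                RuntimeWarning,
                stacklevel=2,
            )
            iqr = np.where(zero, 1.0, iqr)
        self.scale_ = iqr
        self.seen_ids_ = None if row_ids is None else np.asarray(row_ids)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise DataError("robust scaler used before fit")
        X = np.asarray(X, float)
        if X.shape[1] != self.center_.shape[0]:
            raise DataError(
                f"feature count {X.shape[1]} differs from fit-time {self.center_.shape[0]}"
            )
        return (X - self.center_) / self.scale_

    def fit_transform(self, X: np.ndarray, row_ids: np.ndarray | None = None) -> np.ndarray:
        return self.fit(X, row_ids=row_ids).transform(X)


@dataclass(frozen=True)
class PCAConfig:
    """Incremental-PCA settings for the voxel pipeline.

    ``scope="fold"`` refits the basis inside every CV training fold
    (leakage-safe default); ``scope="global"`` fits once on the full training
    site, the cheaper variant.
    """

    n_components: int = 150
    batch_size: int = 400
    scope: str = "fold"

    def __post_init__(self) -> None:
        if self.n_components >= self.batch_size:
            raise ParameterError(
                f"n_components ({self.n_components}) must be lower than "
                f"batch_size ({self.batch_size})"
            )
        if self.scope not in ("fold", "global"):
            raise ParameterError("pca scope must be 'fold' or 'global'")


class IncrementalPCABasis:
    """Incremental PCA basis with a deterministic sign convention.

    Wraps :class:`sklearn.decomposition.IncrementalPCA`; memory use scales
    with ``batch_size`` x features rather than subjects x features.  Each
    component is flipped so its largest-magnitude loading is positive, making
    scores reproducible across runs and platforms.
    """

    def __init__(self, n_components: int = 150, batch_size: int = 400) -> None:
        if n_components >= batch_size:
            raise ParameterError(
                f"n_components ({n_components}) must be lower than batch_size ({batch_size})"
            )
        self.n_components = n_components
        self.batch_size = batch_size
        self.components_: np.ndarray | None = None
        self.mean_: np.ndarray | None = None
        self.explained_variance_ratio_: np.ndarray | None = None
        self.seen_ids_: np.ndarray | None = None

    @property
    def fitted(self) -> bool:
        return self.components_ is not None

    def fit(self, X: np.ndarray, row_ids: np.ndarray | None = None) -> "IncrementalPCABasis":
        X = np.asarray(X, float)
        if min(X.shape) < self.n_components:
            raise ParameterError(
                f"incremental PCA needs at least n_components={self.n_components} "
                f"samples and features, got shape {X.shape}"
            )
        ipca = IncrementalPCA(n_components=self.n_components, batch_size=self.batch_size)
        ipca.fit(X)
        comps = ipca.components_
        flip = np.sign(comps[np.arange(comps.shape[0]), np.argmax(np.abs(comps), axis=1)])
        flip[flip == 0] = 1.0
        self.components_ = comps * flip[:, None]
        self.mean_ = ipca.mean_
        self.explained_variance_ratio_ = ipca.explained_variance_ratio_
        self.seen_ids_ = None if row_ids is None else np.asarray(row_ids)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise DataError("PCA basis used before fit")
        X = np.asarray(X, float)
        return (X - self.mean_) @ self.components_.T

    def fit_transform(self, X: np.ndarray, row_ids: np.ndarray | None = None) -> np.ndarray:
        return self.fit(X, row_ids=row_ids).transform(X)

    @property
    def total_explained_variance_ratio_(self) -> float:
        if not self.fitted:
            raise DataError("PCA basis used before fit")
        return float(np.sum(self.explained_variance_ratio_))
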