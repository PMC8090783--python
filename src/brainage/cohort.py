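"""Synthetic cohorts with the statistical structure of population morphometry studies.

The generators emulate, at desk scale, the kind of data a large two-site
structural-MRI ageing study produces after image processing:

* integer chronological ages on a bounded range (default 47-73 years),
  uniformly or near-uniformly distributed, with near-balanced sex;
* ~101 region-level volumes that shrink roughly linearly with age, carry a
  small sex effect, scale with head size (total intracranial volume, TIV)
  and contain a few heavy-tailed outliers;
* high-dimensional "voxel" feature vectors with low-rank spatial redundancy,
  where the age signal lives in a small latent subspace plus isotropic noise;
* a second acquisition site whose age distribution is shifted slightly older,
  while the feature-generating law is shared between sites.

A shared per-subject latent (``brain_age_sd``) shifts every feature as if the
brain were a few years older or younger than the calendar age.  This bounds
the accuracy any regressor can reach, which is what keeps desk-scale mean
absolute errors in the empirically plausible 3-5 year band rather than
collapsing to zero as features accumulate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "RegionFeatureModel",
    "VoxelFeatureModel",
    "Cohort",
    "generate_region_cohort",
    "generate_voxel_cohort",
    "split_sites",
    "default_site_specs",
]

_SEX_LEVELS = ("M", "F")


class ParameterError(ValueError):
    """Invalid generator specification."""


@dataclass(frozen=True)
class CohortSpec:
    """Demographic design of one synthetic site.

    ``age_distribution`` is ``"uniform"`` (independent draws), ``"balanced"``
    (exactly equal counts per integer age, sexes balanced within age when
    divisible) or a mapping ``{age: weight}``.  ``site_age_shift`` tilts the
    sampling weights so the realised mean age moves by approximately that many
    years, emulating a second site with an older intake.
    """

    n_subjects: int
    age_min: int = 47
    age_max: int = 73
    age_distribution: Union[str, dict] = "uniform"
    sex_balance: float = 0.5
    site: str = "site1"
    site_age_shift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.age_min >= self.age_max:
            raise ParameterError(f"age_min ({self.age_min}) must be < age_max ({self.age_max})")
        if not 0.0 <= self.sex_balance <= 1.0:
            raise ParameterError(f"sex_balance must lie in [0, 1], got {self.sex_balance}")
        if self.n_subjects < 2:
            raise ParameterError("n_subjects must be at least 2")
        if self.age_distribution == "balanced" and self.n_subjects < 2 * self.n_ages:
            raise ParameterError(
                "balanced sampling needs n_subjects >= 2 * number of integer ages "
                f"({2 * self.n_ages}), got {self.n_subjects}"
            )
        if isinstance(self.age_distribution, dict):
            ages = set(self.age_distribution)
            if not ages <= set(range(self.age_min, self.age_max + 1)):
                raise ParameterError("age weights outside [age_min, age_max]")

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.age_min, self.age_max + 1)

    @property
    def n_ages(self) -> int:
        return self.age_max - self.age_min + 1


def _age_weights(spec: CohortSpec) -> np.ndarray:
    grid = spec.ages.astype(float)
    if isinstance(spec.age_distribution, dict):
        w = np.array([spec.age_distribution.get(int(a), 0.0) for a in grid], float)
    else:
        w = np.ones_like(grid)
    if spec.site_age_shift:
        # linear tilt: for uniform base weights the mean shifts by ~site_age_shift
        centre = grid.mean()
        var = np.average((grid - centre) ** 2, weights=w)
        w = w * np.clip(1.0 + spec.site_age_shift * (grid - centre) / var, 1e-6, None)
    return w / w.sum()


def _sample_demographics(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    grid = spec.ages
    if spec.age_distribution == "balanced":
        base, extra = divmod(spec.n_subjects, spec.n_ages)
        counts = np.full(spec.n_ages, base)
        if extra:
            counts[rng.choice(spec.n_ages, size=extra, replace=False)] += 1
        ages, sexes = [], []
        for a, c in zip(grid, counts):
            ages.extend([a] * c)
            n_f = int(round(c * spec.sex_balance))
            sex = np.array(["F"] * n_f + ["M"] * (c - n_f))
            rng.shuffle(sex)
            sexes.extend(sex)
        age = np.array(ages)
        sex = np.array(sexes)
    else:
        age = rng.choice(grid, size=spec.n_subjects, p=_age_weights(spec))
        sex = np.where(rng.random(spec.n_subjects) < spec.sex_balance, "F", "M")
    ids = [f"{spec.site}-{i:06d}" for i in range(spec.n_subjects)]
    return pd.DataFrame({"id": ids, "age": age.astype(int), "sex": sex, "site": spec.site})


@dataclass(eq=False)
class RegionFeatureModel:
    """Linear-atrophy generative law for region-level volumes.

    Region ``r`` of subject ``i`` (before TIV coupling) is::

        a_r + b_r * (age_i + u_i - age_center) + c_r * 1[sex=F] + eps_ir

    with ``u_i ~ N(0, brain_age_sd^2)`` shared across regions and
    ``eps_ir ~ N(0, noise_sd_r^2)`` independent.  A fraction ``outlier_rate``
    of entries is shifted by +-5 noise SDs (heavy-tailed contamination).
    When ``tiv_coupled`` the whole profile scales with the subject's
    lognormal TIV, so dividing by TIV removes head-size variance.
    """

    n_regions: int = 101
    intercepts: np.ndarray | None = None
    slopes: np.ndarray | None = None
    sex_effects: np.ndarray | None = None
    noise_sd: np.ndarray | None = None
    outlier_rate: float = 0.01
    brain_age_sd: float = 4.5
    age_center: float = 60.0
    tiv_log_mean: float = float(np.log(1480.0))
    tiv_log_sd: float = 0.1
    tiv_coupled: bool = True
    param_seed: int = 12345

    def __post_init__(self) -> None:
        if not 0.0 <= self.outlier_rate < 0.1:
            raise ParameterError("outlier_rate must lie in [0, 0.1)")
        prng = np.random.default_rng(self.param_seed)
        if self.intercepts is None:
            self.intercepts = prng.uniform(5.0, 50.0, self.n_regions)
        if self.slopes is None:
            # per-year shrinkage of 0.15-0.45% of the region volume; ~90% of
            # regions atrophy with age, a minority grows slightly (e.g. ventricles)
            frac = prng.uniform(0.0015, 0.0045, self.n_regions)
            sign = np.where(prng.random(self.n_regions) < 0.9, -1.0, 1.0)
            self.slopes = sign * frac * self.intercepts
        if self.sex_effects is None:
            self.sex_effects = prng.normal(-0.01, 0.005, self.n_regions) * self.intercepts
        if self.noise_sd is None:
            self.noise_sd = 0.02 * self.intercepts
        for name in ("intercepts", "slopes", "sex_effects", "noise_sd"):
            arr = np.asarray(getattr(self, name), float)
            if arr.shape != (self.n_regions,):
                raise ParameterError(f"{name} must have shape ({self.n_regions},)")
            setattr(self, name, arr)
        if np.any(self.noise_sd <= 0):
            raise ParameterError("noise_sd must be strictly positive")

    def to_dict(self) -> dict:
        return {
            "kind": "region",
            "n_regions": self.n_regions,
            "outlier_rate": self.outlier_rate,
            "brain_age_sd": self.brain_age_sd,
            "age_center": self.age_center,
            "tiv_log_mean": self.tiv_log_mean,
            "tiv_log_sd": self.tiv_log_sd,
            "tiv_coupled": self.tiv_coupled,
            "param_seed": self.param_seed,
        }


@dataclass(eq=False)
class VoxelFeatureModel:
    """Low-rank-plus-noise generative law for voxel-style features.

    ``X = L Q + sigma_n E`` with orthonormal loading rows ``Q`` (k x p).
    Latent 0 is linear in ``age + u_i`` and carries ``age_signal_fraction``
    of the total latent variance; the remaining latents are pure nuisance
    with polynomially decaying scales (the "spatial redundancy").
    """

    n_voxels: int = 10_000
    n_latents: int = 200
    age_signal_fraction: float = 0.3
    latent_decay: float = 0.5
    noise_variance_fraction: float = 0.35
    noise_sd: float | None = None
    brain_age_sd: float = 3.0
    loading_seed: int = 54321

    def __post_init__(self) -> None:
        if self.n_latents > self.n_voxels:
            raise ParameterError(
                f"n_latents ({self.n_latents}) must not exceed n_voxels ({self.n_voxels})"
            )
        if not 0.0 < self.age_signal_fraction < 1.0:
            raise ParameterError("age_signal_fraction must lie in (0, 1)")
        if not 0.0 <= self.noise_variance_fraction < 1.0:
            raise ParameterError("noise_variance_fraction must lie in [0, 1)")

    def latent_scales(self) -> np.ndarray:
        """Per-latent SDs; index 0 is the age latent."""
        j = np.arange(1, self.n_latents)
        tau = j.astype(float) ** (-self.latent_decay)
        tau *= np.sqrt(1.0 / np.sum(tau**2))  # nuisance variance sums to 1
        f = self.age_signal_fraction
        s_age = np.sqrt(f / (1.0 - f))
        return np.concatenate([[s_age], tau])

    def effective_noise_sd(self) -> float:
        if self.noise_sd is not None:
            return float(self.noise_sd)
        total_latent = float(np.sum(self.latent_scales() ** 2))
        nu = self.noise_variance_fraction
        return float(np.sqrt(nu / (1.0 - nu) * total_latent / self.n_voxels))

    def loadings(self) -> np.ndarray:
        """Orthonormal k x p loading matrix, fixed by ``loading_seed``."""
        prng = np.random.default_rng(self.loading_seed)
        a = prng.standard_normal((self.n_voxels, self.n_latents))
        q, _ = np.linalg.qr(a)
        return q.T  # rows orthonormal

    def to_dict(self) -> dict:
        return {
            "kind": "voxel",
            "n_voxels": self.n_voxels,
            "n_latents": self.n_latents,
            "age_signal_fraction": self.age_signal_fraction,
            "latent_decay": self.latent_decay,
            "noise_variance_fraction": self.noise_variance_fraction,
            "noise_sd": self.noise_sd,
            "brain_age_sd": self.brain_age_sd,
            "loading_seed": self.loading_seed,
        }


@dataclass(eq=False)
class Cohort:
    """One site's subjects plus their feature block.

    ``subjects`` holds id/age/sex/site (and tiv for region cohorts);
    ``features`` is the aligned subjects x features matrix.
    """

    subjects: pd.DataFrame
    features: np.ndarray
    feature_kind: str  # "region" | "voxel" | "component"
    feature_names: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, float)
        required = {"id", "age", "sex", "site"}
        missing = required - set(self.subjects.columns)
        if missing:
            raise ParameterError(f"subject table missing columns: {sorted(missing)}")
        if self.subjects[list(required)].isna().any().any():
            raise ParameterError("subject table contains missing values")
        if len(self.subjects) != self.features.shape[0]:
            raise ParameterError("feature block row count must equal subject count")
        if not self.feature_names:
            width = len(str(self.features.shape[1]))
            self.feature_names = [
                f"feature_{i + 1:0{max(width, 4)}d}" for i in range(self.features.shape[1])
            ]
        self.subjects = self.subjects.reset_index(drop=True)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def ages(self) -> np.ndarray:
        return self.subjects["age"].to_numpy(int)

    @property
    def sex(self) -> np.ndarray:
        return self.subjects["sex"].to_numpy(str)

    @property
    def ids(self) -> np.ndarray:
        return self.subjects["id"].to_numpy(str)

    @property
    def tiv(self) -> np.ndarray:
        if "tiv" not in self.subjects.columns:
            raise ParameterError("cohort has no TIV column")
        return self.subjects["tiv"].to_numpy(float)

    def subset(self, idx: np.ndarray) -> "Cohort":
        idx = np.asarray(idx)
        return Cohort(
            subjects=self.subjects.iloc[idx].reset_index(drop=True),
            features=self.features[idx],
            feature_kind=self.feature_kind,
            feature_names=list(self.feature_names),
            provenance=dict(self.provenance),
        )

    def to_tsv(self, path: str | Path) -> Path:
        """Write subjects + features as one TSV plus a JSON sidecar."""
        path = Path(path)
        feats = pd.DataFrame(self.features, columns=self.feature_names)
        table = pd.concat([self.subjects.reset_index(drop=True), feats], axis=1)
        table.to_csv(path, sep="\t", index=False)
        sidecar = {
            "feature_kind": self.feature_kind,
            "n_subjects": self.n_subjects,
            "n_features": int(self.features.shape[1]),
            "provenance": _jsonable(self.provenance),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
        return path

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Cohort":
        path = Path(path)
        table = pd.read_csv(path, sep="\t", float_precision="round_trip")
        sidecar_path = path.with_suffix(path.suffix + ".json")
        provenance, kind = {}, "region"
        if sidecar_path.exists():
            sidecar = json.loads(sidecar_path.read_text())
            provenance = sidecar.get("provenance", {})
            kind = sidecar.get("feature_kind", "region")
        meta_cols = [c for c in ("id", "age", "sex", "site", "tiv") if c in table.columns]
        feat_cols = [c for c in table.columns if c not in meta_cols]
        return cls(
            subjects=table[meta_cols],
            features=table[feat_cols].to_numpy(float),
            feature_kind=kind,
            feature_names=feat_cols,
            provenance=provenance,
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def generate_region_cohort(
    spec: CohortSpec, model: RegionFeatureModel | None = None
) -> Cohort:
    """Draw a region-volume cohort; deterministic given ``spec.seed``."""
    model = model or RegionFeatureModel()
    rng = np.random.default_rng(spec.seed)
    demo = _sample_demographics(spec, rng)
    n = len(demo)
    age = demo["age"].to_numpy(float)
    is_f = (demo["sex"] == "F").to_numpy(float)

    u = rng.normal(0.0, model.brain_age_sd, n) if model.brain_age_sd > 0 else np.zeros(n)
    eps = rng.normal(0.0, 1.0, (n, model.n_regions)) * model.noise_sd
    x = (
        model.intercepts
        + np.outer(age + u - model.age_center, model.slopes)
        + np.outer(is_f, model.sex_effects)
        + eps
    )
    if model.outlier_rate > 0:
        mask = rng.random(x.shape) < model.outlier_rate
        signs = np.where(rng.random(x.shape) < 0.5, -1.0, 1.0)
        x = x + mask * signs * 5.0 * model.noise_sd
    tiv = rng.lognormal(model.tiv_log_mean, model.tiv_log_sd, n)
    if model.tiv_coupled:
        x = x * (tiv / np.exp(model.tiv_log_mean))[:, None]
    demo = demo.assign(tiv=tiv)
    width = len(str(model.n_regions))
    names = [f"region_{i + 1:0{max(width, 3)}d}" for i in range(model.n_regions)]
    return Cohort(
        subjects=demo,
        features=x,
        feature_kind="region",
        feature_names=names,
        provenance={"spec": spec.__dict__ | {}, "model": model.to_dict()},
    )


def generate_voxel_cohort(
    spec: CohortSpec, model: VoxelFeatureModel | None = None
) -> Cohort:
    """Draw a voxel-style cohort (low-rank latents x orthonormal loadings + noise)."""
    model = model or VoxelFeatureModel()
    rng = np.random.default_rng(spec.seed)
    demo = _sample_demographics(spec, rng)
    n = len(demo)
    age = demo["age"].to_numpy(float)

    scales = model.latent_scales()
    u = rng.normal(0.0, model.brain_age_sd, n) if model.brain_age_sd > 0 else np.zeros(n)
    grid = spec.ages.astype(float)
    age_sd = np.sqrt(np.var(grid) + model.brain_age_sd**2)
    latents = np.empty((n, model.n_latents))
    latents[:, 0] = scales[0] * (age + u - grid.mean()) / age_sd
    latents[:, 1:] = rng.standard_normal((n, model.n_latents - 1)) * scales[1:]

    x = latents @ model.loadings()
    sigma_n = model.effective_noise_sd()
    if sigma_n > 0:
        x = x + sigma_n * rng.standard_normal((n, model.n_voxels))
    width = len(str(model.n_voxels))
    names = [f"voxel_{i + 1:0{max(width, 5)}d}" for i in range(model.n_voxels)]
    return Cohort(
        subjects=demo,
        features=x,
        feature_kind="voxel",
        feature_names=names,
        provenance={"spec": spec.__dict__ | {}, "model": model.to_dict()},
    )


def generate_cohort(spec: CohortSpec, model) -> Cohort:
    if isinstance(model, RegionFeatureModel):
        return generate_region_cohort(spec, model)
    if isinstance(model, VoxelFeatureModel):
        return generate_voxel_cohort(spec, model)
    raise ParameterError(f"unknown feature model type: {type(model).__name__}")


def split_sites(spec1: CohortSpec, spec2: CohortSpec, model) -> tuple[Cohort, Cohort]:
    """Generate two disjoint site cohorts under a shared feature-generating law.

    Site 2 inherits the same region/voxel model; only the demographic spec
    (in particular ``site_age_shift``) differs, so any generalisation gap is
    purely demographic, not a change in the features' law.
    """
    if spec1.site == spec2.site:
        spec2 = replace(spec2, site=spec1.site + "b")
    if spec1.seed == spec2.seed:
        spec2 = replace(spec2, seed=spec2.seed + 1_000_003)
    return generate_cohort(spec1, model), generate_cohort(spec2, model)


def default_site_specs(
    n_site1: int = 2000,
    n_site2: int = 350,
    site_age_shift: float = 1.1,
    seed: int = 0,
) -> tuple[CohortSpec, CohortSpec]:
    """Two-site design at ~1/5 of the full-study scale (site 2 slightly older)."""
    return (
        CohortSpec(n_subjects=n_site1, site="site1", seed=seed),
        CohortSpec(
            n_subjects=n_site2,
            site="site2",
            site_age_shift=site_age_shift,
            seed=seed + 1_000_003,
        ),
    )
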