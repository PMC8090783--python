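"""Model/Results facade for the full brain-age benchmarking analysis.

:class:`BrainAgeBenchmark` is built from the data (one or two feature
representations of the same subjects, plus optionally an independent site);
``fit()`` runs the repeated stratified CV over the configured model suite
and returns a :class:`BenchmarkResults` carrying fold scores, per-model
summaries, the corrected pairwise comparison matrix, and hooks for the
generalisation and learning-curve analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import (
    Cohort,
    CohortSpec,
    ParameterError,
    RegionFeatureModel,
    VoxelFeatureModel,
    default_site_specs,
    generate_region_cohort,
    generate_voxel_cohort,
)
from .evaluation import (
    ComparisonMatrix,
    CVPlan,
    CVResult,
    ModelSpec,
    _resolve_cohorts,
    assert_no_leakage,
    default_model_suite,
    run_repeated_cv,
)
from .generalisation import GeneralisationResult, apply_to_site, compare_site_ages
from .learning_curves import LearningCurve, SizeGrid, bootstrap_curve, chance_level_mae
from .preprocessing import PCAConfig

__all__ = ["BrainAgeBenchmark", "BenchmarkResults", "simulate_two_site_study"]


def simulate_two_site_study(
    n_site1: int = 2000,
    n_site2: int = 350,
    site_age_shift: float = 1.1,
    n_voxels: int = 10_000,
    seed: int = 0,
    region_model: RegionFeatureModel | None = None,
    voxel_model: VoxelFeatureModel | None = None,
    include_voxel: bool = True,
) -> tuple[dict[str, Cohort], dict[str, Cohort]]:
    """Generate matched region+voxel cohorts for two sites.

    Within a site the region and voxel cohorts share the same subjects
    (identical demographic draws from the same seed); site 2 is sampled
    slightly older via ``site_age_shift`` under the same feature law.
    Returns ``(site1_cohorts, site2_cohorts)`` as ``{"region": ..., "voxel": ...}``.
    """
    spec1, spec2 = default_site_specs(n_site1, n_site2, site_age_shift, seed)
    region_model = region_model or RegionFeatureModel()
    site1 = {"region": generate_region_cohort(spec1, region_model)}
    site2 = {"region": generate_region_cohort(spec2, region_model)}
    if include_voxel:
        voxel_model = voxel_model or VoxelFeatureModel(n_voxels=n_voxels)
        site1["voxel"] = generate_voxel_cohort(spec1, voxel_model)
        site2["voxel"] = generate_voxel_cohort(spec2, voxel_model)
    return site1, site2


class BrainAgeBenchmark:
    """The benchmarking model: a suite of regressors bound to cohort data.

    Parameters
    ----------
    cohorts : Cohort or {"region": Cohort, "voxel": Cohort}
        Training-site data; representations must share subjects.
    models : list[ModelSpec], optional
        Defaults to the eight-model suite (3 region, 2 raw voxel, 3 voxel+PCA),
        trimmed to the representations available in ``cohorts``.
    plan : CVPlan
        Repeated stratified CV design (default 10x10 with nested 5-fold C search).
    pca : PCAConfig
        Incremental-PCA settings for the voxel_pca representation.
    """

    def __init__(
        self,
        cohorts,
        models: list[ModelSpec] | None = None,
        plan: CVPlan = CVPlan(),
        pca: PCAConfig = PCAConfig(),
    ) -> None:
        self.cohorts = _resolve_cohorts(cohorts)
        if models is None:
            models = [
                s
                for s in default_model_suite()
                if ("voxel" if s.representation.startswith("voxel") else "region")
                in self.cohorts
            ]
        if not models:
            raise ParameterError("no models to benchmark")
        self.models = models
        self.plan = plan
        self.pca = pca

    @classmethod
    def from_synthetic(
        cls,
        n_subjects: int = 2000,
        n_voxels: int = 10_000,
        seed: int = 0,
        include_voxel: bool = True,
        **kwargs,
    ) -> "BrainAgeBenchmark":
        """Build the benchmark on a freshly generated single-site cohort."""
        site1, _ = simulate_two_site_study(
            n_site1=n_subjects, n_site2=54, n_voxels=n_voxels, seed=seed,
            include_voxel=include_voxel,
        )
        return cls(site1, **kwargs)

    def fit(self, keep_models: bool = True, progress: bool = False) -> "BenchmarkResults":
        """Run the repeated CV benchmark and return the results object."""
        cv = run_repeated_cv(
            self.cohorts,
            self.models,
            self.plan,
            pca_config=self.pca,
            keep_models=keep_models,
            progress=progress,
        )
        return BenchmarkResults(benchmark=self, cv=cv)


@dataclass(eq=False)
class BenchmarkResults:
    """Fitted benchmark: fold scores, model instances, comparisons, summaries."""

    benchmark: BrainAgeBenchmark
    cv: CVResult
    _generalisation: GeneralisationResult | None = field(default=None, repr=False)

    @property
    def scores(self) -> pd.DataFrame:
        return self.cv.scores

    def summary(self) -> pd.DataFrame:
        """Mean (SD) per model of MAE, weighted MAE, RMSE, r, prediction R^2, age bias."""
        return self.cv.summary()

    def summary_text(self) -> str:
        s = self.summary()
        cols = ["mae", "weighted_mae", "rmse", "pearson_r", "prediction_r2", "age_bias"]
        lines = [
            "Cross-validation performance ({} records per model)".format(
                self.benchmark.plan.n_scores
            ),
            "",
            f"{'model':<16}" + "".join(f"{c:>16}" for c in cols),
        ]
        for m, row in s.iterrows():
            cells = []
            for c in cols:
                v, sd = row[c], row.get(f"{c}_sd", np.nan)
                cells.append(
                    f"{v:.2f} ({sd:.2f})" if np.isfinite(v) and np.isfinite(sd) else
                    ("n/a" if not np.isfinite(v) else f"{v:.2f}")
                )
            lines.append(f"{m:<16}" + "".join(f"{c:>16}" for c in cells))
        return "\n".join(lines)

    def compare(self, metric: str = "mae", alpha: float = 0.05) -> ComparisonMatrix:
        return self.cv.compare(metric=metric, alpha=alpha)

    def check_no_leakage(self) -> None:
        assert_no_leakage(self.cv)

    def generalise(self, site_cohorts) -> GeneralisationResult:
        """Score every trained instance on an independent-site cohort."""
        self._generalisation = apply_to_site(self.cv, site_cohorts)
        return self._generalisation

    def compare_site_ages(self, site_cohorts, equal_var: bool = False) -> tuple[float, float]:
        if isinstance(site_cohorts, Cohort):
            ages2 = site_cohorts.ages
        else:
            ages2 = next(iter(site_cohorts.values())).ages
        ages1 = next(iter(self.benchmark.cohorts.values())).ages
        return compare_site_ages(ages1, ages2, equal_var=equal_var)

    def learning_curve(
        self,
        grid: SizeGrid = SizeGrid(),
        site_cohorts=None,
        models: list[ModelSpec] | None = None,
    ) -> LearningCurve:
        """Bootstrap learning-curve analysis on the benchmark's cohorts."""
        return bootstrap_curve(
            self.benchmark.cohorts,
            models or self.benchmark.models,
            grid=grid,
            site2_cohorts=site_cohorts,
            plan=self.benchmark.plan,
            pca_config=self.benchmark.pca,
        )

    @property
    def chance_level(self) -> float:
        ages = next(iter(self.benchmark.cohorts.values())).ages
        return chance_level_mae(float(ages.min()), float(ages.max()))
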