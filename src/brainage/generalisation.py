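"""Generalisation of CV-trained models to an independent acquisition site.

Every one of the k*r model instances produced by repeated CV is applied,
with its own training-fold scaler / PCA basis, to the full independent-site
cohort.  Metrics are aggregated as mean (SD) over instances, and the same
variance-corrected paired t-test compares models on their per-instance MAEs.
No independent-site row ever enters a fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, ParameterError
from .evaluation import (
    ComparisonMatrix,
    CVResult,
    _base_kind,
    _fold_metrics,
    compare_all,
)
from .preprocessing import DataError

__all__ = ["GeneralisationResult", "apply_to_site", "compare_site_ages"]


@dataclass(eq=False)
class GeneralisationResult:
    """Per-instance independent-site metrics for every benchmark model."""

    scores: pd.DataFrame  # model, repetition, fold (instance), metrics
    site: str
    n_subjects: int

    def summary(self) -> pd.DataFrame:
        metrics = ["mae", "weighted_mae", "rmse", "pearson_r", "prediction_r2", "age_bias"]
        rows = []
        for m in dict.fromkeys(self.scores["model"]):
            sub = self.scores[self.scores["model"] == m]
            row = {"model": m, "n_instances": len(sub)}
            for met in metrics:
                vals = sub[met].to_numpy(float)
                ok = np.isfinite(vals)
                row[met] = float(np.mean(vals[ok])) if ok.any() else np.nan
                row[f"{met}_sd"] = float(np.std(vals[ok], ddof=1)) if ok.sum() > 1 else np.nan
                if met == "pearson_r" and not ok.all():
                    row["pearson_r_note"] = "n/a for constant-prediction instances"
            rows.append(row)
        return pd.DataFrame(rows).set_index("model")

    def compare(self, metric: str = "mae", alpha: float = 0.05) -> ComparisonMatrix:
        return compare_all(self.scores, metric=metric, alpha=alpha)


def apply_to_site(cv_result: CVResult, site_cohorts) -> GeneralisationResult:
    """Apply every trained CV instance to the independent-site cohort(s).

    ``site_cohorts`` is a Cohort or ``{"region": ..., "voxel": ...}`` mapping
    holding the independent site's subjects.  Each instance transforms the
    test features with its own training statistics before predicting.

    The per-instance score table keeps the originating (repetition, fold)
    labels, so :meth:`GeneralisationResult.compare` retains the paired design
    and the fold-derived train/test ratio of the CV — models are unchanged,
    only the evaluation sample differs.
    """
    if isinstance(site_cohorts, Cohort):
        site_cohorts = {site_cohorts.feature_kind: site_cohorts}
    if not cv_result.trained or not any(cv_result.trained.values()):
        raise ParameterError("CV result holds no trained models (keep_models=False?)")

    n_train = float(cv_result.scores["n_train"].mean())
    n_test = float(cv_result.scores["n_test"].mean())
    records = []
    site_name = None
    n_subjects = None
    for name, instances in cv_result.trained.items():
        for tm in instances:
            kind = _base_kind(tm.representation)
            if kind not in site_cohorts:
                raise DataError(f"model '{name}' needs a '{kind}' cohort for the test site")
            cohort = site_cohorts[kind]
            site_name = cohort.subjects["site"].iloc[0]
            n_subjects = cohort.n_subjects
            y = cohort.ages.astype(float)
            pred = tm.predict_cohort(cohort)
            records.append(
                {
                    "model": name,
                    "repetition": tm.metadata.get("repetition", 0),
                    "fold": tm.metadata.get("fold", 0),
                    "n_train": n_train,
                    "n_test": n_test,
                    **_fold_metrics(y, pred),
                    "n_relevance_vectors": tm.metadata.get("n_relevance_vectors", np.nan),
                    "underfit": tm.metadata.get("underfit", False),
                }
            )
    return GeneralisationResult(
        scores=pd.DataFrame.from_records(records),
        site=str(site_name),
        n_subjects=int(n_subjects),
    )


def compare_site_ages(
    ages_site1: np.ndarray, ages_site2: np.ndarray, equal_var: bool = False
) -> tuple[float, float]:
    """Two-sample t-test on the age distributions of the two sites.

    Welch's test by default (unequal n and variances across sites);
    ``equal_var=True`` gives the classical pooled-variance statistic.
    """
    a = np.asarray(ages_site1, float)
    b = np.asarray(ages_site2, float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both age samples must be non-empty")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)
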