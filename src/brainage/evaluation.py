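"""Repeated stratified cross-validation, metrics, and corrected model comparison.

The protocol: 10-times repeated 10-fold CV stratified by integer age, giving
k*r = 100 performance records per model.  SVR's regularisation weight C is
chosen inside every outer training fold by a 5-fold age-stratified nested
search over a log2 grid, scored by MAE.  All models share the same fold
assignments per repetition (a paired design), which is what licenses the
variance-corrected paired t-test used for the pairwise comparisons:

    t = dbar / sqrt(s_d^2 * (1/(k r) + n_test/n_train))

with k*r - 1 degrees of freedom — the Nadeau-Bengio correction for the
optimistic variance of the classical paired t-test under overlapping CV
training sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, ParameterError
from .preprocessing import (
    DataError,
    IncrementalPCABasis,
    PCAConfig,
    RobustScaler,
    normalise_by_tiv,
)
from .regressors import (
    DegenerateRVRError,
    GPRConfig,
    RVRConfig,
    SVRConfig,
    TrainedModel,
    fit_gpr,
    fit_rvr,
    fit_svr,
)

__all__ = [
    "CVPlan",
    "ModelSpec",
    "CVResult",
    "ComparisonMatrix",
    "brainage",
    "weighted_mae",
    "prediction_r2",
    "age_bias",
    "mae",
    "rmse",
    "pearson_r",
    "stratified_folds",
    "nested_select_C",
    "run_repeated_cv",
    "corrected_paired_ttest",
    "compare_all",
    "default_model_suite",
    "assert_no_leakage",
]

DEFAULT_C_GRID = (2.0**-7, 2.0**-5, 2.0**-3, 2.0**-1, 1.0, 2.0, 2.0**3, 2.0**5, 2.0**7)


# ---------------------------------------------------------------------------
# Metrics


def brainage(predicted: np.ndarray, chronological: np.ndarray) -> np.ndarray:
    """Brain-age gap: predicted minus chronological age (positive = older-looking brain)."""
    predicted = np.asarray(predicted, float)
    chronological = np.asarray(chronological, float)
    if not (np.all(np.isfinite(predicted)) and np.all(np.isfinite(chronological))):
        raise DataError("non-finite ages in BrainAGE computation")
    return predicted - chronological


def mae(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    return float(np.mean(np.abs(brainage(y_pred, y_true))))


def rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    return float(np.sqrt(np.mean(brainage(y_pred, y_true) ** 2)))


def weighted_mae(mae_value: float, age_min: float, age_max: float) -> float:
    """MAE divided by the evaluation set's age range (dimensionless)."""
    if age_max <= age_min:
        raise ParameterError("age_max must exceed age_min")
    return float(mae_value) / (age_max - age_min)


def prediction_r2(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Held-out R^2 (q^2): 1 - SS_res/SS_tot; can be negative.

    Distinct from the squared Pearson correlation: it penalises any error
    between prediction and observation, not just scatter around a refitted line.
    """
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if y_true.size < 2:
        raise ParameterError("prediction R^2 needs at least 2 subjects")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    if ss_tot == 0:
        return np.nan
    return 1.0 - ss_res / ss_tot


def pearson_r(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Pearson correlation; NaN when either input has no variance."""
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if np.std(y_true) == 0 or np.std(y_pred) == 0:
        return np.nan
    return float(stats.pearsonr(y_true, y_pred)[0])


def age_bias(chronological: np.ndarray, brainage_values: np.ndarray) -> float:
    """Spearman rank correlation between age and BrainAGE (ties by average rank).

    Strongly negative values indicate regression to the mean.  Returns NaN
    ("not available") when either input is constant, e.g. a degenerate model
    predicting the same age for everyone.
    """
    chronological = np.asarray(chronological, float)
    brainage_values = np.asarray(brainage_values, float)
    if chronological.size < 3:
        raise ParameterError("age bias needs at least 3 subjects")
    if np.std(chronological) == 0 or np.std(brainage_values) == 0:
        return np.nan
    return float(stats.spearmanr(chronological, brainage_values)[0])


def _fold_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    gap = brainage(y_pred, y_true)
    m = mae(y_true, y_pred)
    amin, amax = float(np.min(y_true)), float(np.max(y_true))
    return {
        "mae": m,
        "weighted_mae": weighted_mae(m, amin, amax) if amax > amin else np.nan,
        "rmse": rmse(y_true, y_pred),
        "pearson_r": pearson_r(y_true, y_pred),
        "prediction_r2": prediction_r2(y_true, y_pred),
        "age_bias": age_bias(y_true, gap),
    }


# ---------------------------------------------------------------------------
# Fold construction


def _merge_small_strata(ages: np.ndarray, k: int) -> np.ndarray:
    """Map each age to a stratum label, merging ages with < k members into the
    nearest age (ties to the lower age) until every stratum holds >= k."""
    ages = np.asarray(ages)
    labels = ages.astype(float).copy()
    while True:
        uniq, counts = np.unique(labels, return_counts=True)
        if uniq.size <= 1 or counts.min() >= k:
            break
        i = int(np.argmin(counts))
        small = uniq[i]
        others = np.delete(uniq, i)
        nearest = others[np.lexsort((others, np.abs(others - small)))][0]
        labels[labels == small] = nearest
    return labels


def stratified_folds(ages: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Deterministic age-stratified fold assignment (labels 0..k-1).

    Within every age stratum the subjects are shuffled and dealt round-robin
    into folds starting at a random offset, so per-age counts across folds
    differ by at most one.  Ages with fewer than ``k`` members are merged with
    the nearest age before assignment.
    """
    ages = np.asarray(ages)
    n = ages.size
    if k < 2 or k > n:
        raise ParameterError(f"k must lie in [2, n], got {k}")
    rng = np.random.default_rng(seed)
    labels = _merge_small_strata(ages, k)
    folds = np.empty(n, int)
    for stratum in np.unique(labels):
        idx = np.flatnonzero(labels == stratum)
        rng.shuffle(idx)
        start = int(rng.integers(k))
        folds[idx] = (start + np.arange(idx.size)) % k
    return folds


# ---------------------------------------------------------------------------
# Plans and model specifications


@dataclass(frozen=True)
class CVPlan:
    """Repeated stratified CV design with the nested C search grid."""

    k: int = 10
    repetitions: int = 10
    nested_k: int = 5
    c_grid: tuple = DEFAULT_C_GRID
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2 or self.nested_k < 2 or self.repetitions < 1:
            raise ParameterError("invalid CV plan")
        if len(self.c_grid) == 0:
            raise ParameterError("C grid must be non-empty")

    @property
    def n_scores(self) -> int:
        return self.k * self.repetitions


@dataclass(frozen=True)
class ModelSpec:
    """One benchmark entry: a regressor bound to a feature representation."""

    name: str
    regressor: str  # "svr" | "rvr" | "gpr"
    representation: str  # "region" | "voxel" | "voxel_pca"
    config: object | None = None

    def __post_init__(self) -> None:
        if self.regressor not in ("svr", "rvr", "gpr"):
            raise ParameterError(f"unknown regressor '{self.regressor}'")
        if self.representation not in ("region", "voxel", "voxel_pca"):
            raise ParameterError(f"unknown representation '{self.representation}'")
        if self.regressor == "gpr" and self.representation == "voxel":
            raise ParameterError(
                "GPR on raw voxel features is not offered (cost scales with voxels); "
                "use the voxel_pca representation"
            )


def default_model_suite() -> list[ModelSpec]:
    """The eight benchmark models: 3 region, 2 raw-voxel, 3 voxel+PCA."""
    return [
        ModelSpec("svr_region", "svr", "region"),
        ModelSpec("rvr_region", "rvr", "region"),
        ModelSpec("gpr_region", "gpr", "region"),
        ModelSpec("svr_voxel", "svr", "voxel"),
        ModelSpec("rvr_voxel", "rvr", "voxel"),
        ModelSpec("svr_voxel_pca", "svr", "voxel_pca"),
        ModelSpec("rvr_voxel_pca", "rvr", "voxel_pca"),
        ModelSpec("gpr_voxel_pca", "gpr", "voxel_pca"),
    ]


# ---------------------------------------------------------------------------
# Nested hyperparameter search (SVR only)


def nested_select_C(
    X: np.ndarray,
    y: np.ndarray,
    ages: np.ndarray,
    plan: CVPlan,
    seed: int,
    base_config: SVRConfig = SVRConfig(),
    gram: np.ndarray | None = None,
) -> float:
    """Choose C from the grid by inner age-stratified CV, scored by MAE.

    Ties (including duplicate grid entries) break to the smaller C.  When
    ``gram`` is given the inner fits slice the precomputed training Gram
    matrix instead of refitting kernels.
    """
    if len(plan.c_grid) == 0:
        raise ParameterError("C grid must be non-empty")
    grid = sorted(float(c) for c in plan.c_grid)
    if len(grid) == 1:
        return grid[0]
    inner = stratified_folds(np.asarray(ages), plan.nested_k, seed)
    best_c, best_score = None, np.inf
    for c in grid:
        errs = []
        for f in range(plan.nested_k):
            tr = np.flatnonzero(inner != f)
            va = np.flatnonzero(inner == f)
            cfg = replace(base_config, C=c)
            if gram is None:
                model = fit_svr(X[tr], y[tr], cfg)
                pred = model.predict(X[va])
            else:
                cfg = replace(cfg, kernel="precomputed")
                model = fit_svr(
                    gram[np.ix_(tr, tr)], y[tr], cfg, features=X[tr]
                )
                pred = model.predict(X[va])
            errs.append(mae(y[va], pred))
        score = float(np.mean(errs))
        if score < best_score:
            best_c, best_score = c, score
    return best_c


# ---------------------------------------------------------------------------
# Corrected paired t-test and pairwise comparison


def corrected_paired_ttest(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    n_train: float,
    n_test: float,
) -> tuple[float, float]:
    """Variance-corrected paired t-test for repeated k-fold CV scores.

    The per-fold variance is inflated by ``1/(k r) + n_test/n_train`` to
    compensate for the dependence induced by overlapping training sets.
    Returns (t, two-sided p) with k*r - 1 degrees of freedom.
    """
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ParameterError("paired score vectors must share the same length")
    n = a.size
    if n < 2:
        raise ParameterError("need at least two paired scores")
    d = a - b
    dbar = float(d.mean())
    var_d = float(d.var(ddof=1))
    if var_d == 0:
        if dbar == 0:
            return 0.0, 1.0
        return float(np.sign(dbar) * np.inf), 0.0
    se = np.sqrt(var_d * (1.0 / n + n_test / n_train))
    t = dbar / se
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return float(t), p


@dataclass(eq=False)
class ComparisonMatrix:
    """All pairwise corrected t-tests between benchmark models."""

    models: list[str]
    t: pd.DataFrame
    p: pd.DataFrame
    mean_diff: pd.DataFrame
    n_pairs: int
    alpha: float = 0.05

    @property
    def bonferroni_alpha(self) -> float:
        return self.alpha / self.n_pairs

    def significant(self, a: str, b: str) -> bool:
        return bool(self.p.loc[a, b] < self.bonferroni_alpha)

    def pairs(self) -> pd.DataFrame:
        rows = []
        for a, b in combinations(self.models, 2):
            rows.append(
                {
                    "model_a": a,
                    "model_b": b,
                    "t": self.t.loc[a, b],
                    "p": self.p.loc[a, b],
                    "mean_mae_diff": self.mean_diff.loc[a, b],
                    "significant": self.significant(a, b),
                }
            )
        return pd.DataFrame(rows)

    def render(self) -> pd.DataFrame:
        """Upper-triangular "p (t)" table, the layout used for reporting."""
        out = pd.DataFrame("", index=self.models, columns=self.models)
        for a, b in combinations(self.models, 2):
            p, t = self.p.loc[a, b], self.t.loc[a, b]
            cell = f"{p:.2f} ({t:.2f})" if p >= 0.001 else f"<0.001 ({t:.2f})"
            if self.significant(a, b):
                cell = "*" + cell
            out.loc[a, b] = cell
        np.fill_diagonal(out.values, "-")
        return out


def compare_all(
    scores: pd.DataFrame, metric: str = "mae", alpha: float = 0.05
) -> ComparisonMatrix:
    """Corrected pairwise t-tests across all models in a fold-score table.

    Requires the paired design: every model must contribute scores from the
    same (repetition, fold) index sets, in the same order.
    """
    models = list(dict.fromkeys(scores["model"]))
    if len(models) < 2:
        raise ParameterError("need at least two models to compare")
    by_model = {}
    keys = None
    for m in models:
        sub = scores[scores["model"] == m].sort_values(["repetition", "fold"])
        mkeys = list(zip(sub["repetition"], sub["fold"]))
        if keys is None:
            keys = mkeys
        elif mkeys != keys:
            raise ParameterError(
                f"model '{m}' has different (repetition, fold) records; "
                "the corrected t-test requires a paired design"
            )
        by_model[m] = sub
    n_train = float(scores["n_train"].mean())
    n_test = float(scores["n_test"].mean())
    t_df = pd.DataFrame(0.0, index=models, columns=models)
    p_df = pd.DataFrame(1.0, index=models, columns=models)
    d_df = pd.DataFrame(0.0, index=models, columns=models)
    for a, b in combinations(models, 2):
        sa = by_model[a][metric].to_numpy(float)
        sb = by_model[b][metric].to_numpy(float)
        t, p = corrected_paired_ttest(sa, sb, n_train=n_train, n_test=n_test)
        t_df.loc[a, b], t_df.loc[b, a] = t, -t
        p_df.loc[a, b] = p_df.loc[b, a] = p
        d_df.loc[a, b] = float(np.mean(sa - sb))
        d_df.loc[b, a] = -d_df.loc[a, b]
    n_pairs = len(models) * (len(models) - 1) // 2
    return ComparisonMatrix(
        models=models, t=t_df, p=p_df, mean_diff=d_df, n_pairs=n_pairs, alpha=alpha
    )


# ---------------------------------------------------------------------------
# The repeated-CV engine


@dataclass(eq=False)
class CVResult:
    """Fold scores, trained model instances and the leakage-audit trail."""

    scores: pd.DataFrame
    trained: dict[str, list[TrainedModel]]
    fold_assignments: np.ndarray  # repetitions x n_subjects
    plan: CVPlan
    audit: list[dict] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        """Mean (SD) of every metric over the k*r records, per model."""
        metrics = ["mae", "weighted_mae", "rmse", "pearson_r", "prediction_r2", "age_bias"]
        rows = []
        for m in dict.fromkeys(self.scores["model"]):
            sub = self.scores[self.scores["model"] == m]
            row = {"model": m, "n_records": len(sub)}
            for met in metrics:
                vals = sub[met].to_numpy(float)
                ok = np.isfinite(vals)
                row[met] = float(np.mean(vals[ok])) if ok.any() else np.nan
                row[f"{met}_sd"] = float(np.std(vals[ok], ddof=1)) if ok.sum() > 1 else np.nan
            rows.append(row)
        return pd.DataFrame(rows).set_index("model")

    def compare(self, metric: str = "mae", alpha: float = 0.05) -> ComparisonMatrix:
        return compare_all(self.scores, metric=metric, alpha=alpha)


def _spawn_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, np.uint32)[0] % (2**31 - 1))


def _resolve_cohorts(cohorts) -> dict[str, Cohort]:
    if isinstance(cohorts, Cohort):
        cohorts = {cohorts.feature_kind: cohorts}
    if not isinstance(cohorts, dict) or not cohorts:
        raise ParameterError("cohorts must be a Cohort or a {kind: Cohort} mapping")
    ages = None
    for kind, c in cohorts.items():
        if kind not in ("region", "voxel"):
            raise ParameterError(f"unknown cohort kind '{kind}'")
        if ages is None:
            ages = c.ages
        elif not np.array_equal(ages, c.ages):
            raise ParameterError("region and voxel cohorts must hold the same subjects")
    return cohorts


def _base_kind(representation: str) -> str:
    return "voxel" if representation.startswith("voxel") else "region"


def run_repeated_cv(
    cohorts,
    models: list[ModelSpec] | None = None,
    plan: CVPlan = CVPlan(),
    pca_config: PCAConfig = PCAConfig(),
    keep_models: bool = True,
    progress: bool = False,
) -> CVResult:
    """Run the full repeated stratified CV benchmark.

    ``cohorts`` is a single Cohort or ``{"region": ..., "voxel": ...}`` over
    the same subjects.  All models are evaluated on identical fold
    assignments per repetition; per-fold scalers and PCA bases are fitted on
    the training rows only and shared between the models that use the same
    representation.  Every trained instance is retained for reuse by the
    generalisation stage (``keep_models``).
    """
    cohorts = _resolve_cohorts(cohorts)
    models = models if models is not None else default_model_suite()
    for spec in models:
        if _base_kind(spec.representation) not in cohorts:
            raise ParameterError(
                f"model '{spec.name}' needs a '{_base_kind(spec.representation)}' cohort"
            )

    any_cohort = next(iter(cohorts.values()))
    ages = any_cohort.ages
    y = ages.astype(float)
    ids = any_cohort.ids
    n = ages.size

    region = cohorts.get("region")
    region_norm = normalise_by_tiv(region) if region is not None else None
    voxel = cohorts.get("voxel")
    needs_gram = any(s.representation == "voxel" for s in models)
    gram = voxel.features @ voxel.features.T if (voxel is not None and needs_gram) else None

    global_pca = None
    if pca_config.scope == "global" and any(
        s.representation == "voxel_pca" for s in models
    ):
        global_pca = IncrementalPCABasis(pca_config.n_components, pca_config.batch_size)
        global_pca.fit(voxel.features, row_ids=ids)

    master = np.random.SeedSequence(plan.seed)
    rep_seeds = master.spawn(plan.repetitions)

    records: list[dict] = []
    trained: dict[str, list[TrainedModel]] = {s.name: [] for s in models}
    fold_assignments = np.empty((plan.repetitions, n), int)
    audit: list[dict] = []

    for rep in range(plan.repetitions):
        rep_ss = rep_seeds[rep]
        folds = stratified_folds(ages, plan.k, _spawn_int(rep_ss))
        fold_assignments[rep] = folds
        for f in range(plan.k):
            tr = np.flatnonzero(folds != f)
            va = np.flatnonzero(folds == f)
            blocks = _fit_fold_blocks(
                models, region_norm, voxel, gram, tr, ids, pca_config, global_pca
            )
            audit.append(
                {
                    "repetition": rep,
                    "fold": f,
                    "train_ids": ids[tr],
                    "val_ids": ids[va],
                    "fit_seen_ids": {
                        key: obj.seen_ids_
                        for key, obj in blocks["fitted"].items()
                        if obj is not None and obj.seen_ids_ is not None
                    },
                }
            )
            for j, spec in enumerate(models):
                seed = _spawn_int(np.random.SeedSequence((plan.seed, rep, f, j)))
                tm, chosen_c = _fit_one_model(
                    spec, blocks, y, ages, tr, plan, pca_config, seed
                )
                base = cohorts[_base_kind(spec.representation)]
                pred = tm.predict_cohort(base.subset(va))
                rec = {
                    "model": spec.name,
                    "repetition": rep,
                    "fold": f,
                    "n_train": tr.size,
                    "n_test": va.size,
                    **_fold_metrics(y[va], pred),
                    "chosen_C": chosen_c,
                    "n_relevance_vectors": tm.metadata.get("n_relevance_vectors", np.nan),
                    "underfit": tm.metadata.get("underfit", False),
                }
                records.append(rec)
                tm.metadata.update({"repetition": rep, "fold": f, "model": spec.name})
                if keep_models:
                    trained[spec.name].append(tm)
            if progress:
                print(f"repetition {rep + 1}/{plan.repetitions} fold {f + 1}/{plan.k} done")

    scores = pd.DataFrame.from_records(records)
    return CVResult(
        scores=scores,
        trained=trained,
        fold_assignments=fold_assignments,
        plan=plan,
        audit=audit,
    )


def _fit_fold_blocks(
    models, region_norm, voxel, gram, tr, ids, pca_config, global_pca
) -> dict:
    """Fit per-fold transforms once per representation and slice shared blocks."""
    reps = {s.representation for s in models}
    blocks: dict = {"fitted": {}}
    if "region" in reps:
        scaler = RobustScaler()
        z_tr = scaler.fit_transform(region_norm.features[tr], row_ids=ids[tr])
        blocks["region"] = {"X_tr": z_tr, "scaler": scaler}
        blocks["fitted"]["region_scaler"] = scaler
    if "voxel" in reps:
        blocks["voxel"] = {
            "X_tr": voxel.features[tr],
            "gram_tr": gram[np.ix_(tr, tr)],
        }
    if "voxel_pca" in reps:
        if global_pca is not None:
            basis = global_pca
        else:
            basis = IncrementalPCABasis(pca_config.n_components, pca_config.batch_size)
            basis.fit(voxel.features[tr], row_ids=ids[tr])
        scores_tr = basis.transform(voxel.features[tr])
        scaler = RobustScaler()
        z_tr = scaler.fit_transform(scores_tr, row_ids=ids[tr])
        blocks["voxel_pca"] = {"X_tr": z_tr, "pca": basis, "scaler": scaler}
        blocks["fitted"]["pca"] = basis
        blocks["fitted"]["pca_scaler"] = scaler
    return blocks


def _fit_one_model(
    spec: ModelSpec,
    blocks: dict,
    y: np.ndarray,
    ages: np.ndarray,
    tr: np.ndarray,
    plan: CVPlan,
    pca_config: PCAConfig,
    seed: int,
) -> tuple[TrainedModel, float]:
    """Fit one benchmark model on the fold's training block; returns (model, chosen C)."""
    block = blocks[spec.representation]
    y_tr, ages_tr = y[tr], ages[tr]
    chosen_c = np.nan
    if spec.regressor == "svr":
        base_cfg = spec.config or SVRConfig()
        if spec.representation == "voxel":
            chosen_c = nested_select_C(
                block["X_tr"], y_tr, ages_tr, plan, seed, base_cfg, gram=block["gram_tr"]
            )
            cfg = replace(base_cfg, C=chosen_c, kernel="precomputed")
            tm = fit_svr(block["gram_tr"], y_tr, cfg, features=block["X_tr"])
        else:
            chosen_c = nested_select_C(block["X_tr"], y_tr, ages_tr, plan, seed, base_cfg)
            cfg = replace(base_cfg, C=chosen_c, kernel="linear")
            tm = fit_svr(block["X_tr"], y_tr, cfg)
    elif spec.regressor == "rvr":
        cfg = spec.config or RVRConfig()
        try:
            if spec.representation == "voxel":
                cfg = replace(cfg, kernel="precomputed")
                _, tm = fit_rvr(block["gram_tr"], y_tr, cfg, features=block["X_tr"])
            else:
                cfg = replace(cfg, kernel="linear")
                _, tm = fit_rvr(block["X_tr"], y_tr, cfg)
        except DegenerateRVRError as err:
            tm = TrainedModel(
                kind="rvr",
                weights=None,
                intercept=err.fallback_mean,
                metadata={
                    "n_relevance_vectors": 0,
                    "underfit": True,
                    "degenerate": True,
                },
            )
    elif spec.regressor == "gpr":
        cfg = spec.config or GPRConfig()
        cfg = replace(cfg, seed=seed)
        tm = fit_gpr(block["X_tr"], y_tr, cfg)
    else:  # pragma: no cover - guarded by ModelSpec
        raise ParameterError(spec.regressor)
    tm.representation = spec.representation
    if spec.representation == "region":
        tm.tiv_normalised = True
        tm.scaler = block["scaler"]
    elif spec.representation == "voxel_pca":
        tm.pca = block["pca"]
        tm.scaler = block["scaler"]
    tm.metadata["chosen_C"] = chosen_c
    return tm, chosen_c


def assert_no_leakage(result: CVResult) -> None:
    """Structural audit: no validation row entered any per-fold fit."""
    for entry in result.audit:
        val = set(entry["val_ids"])
        for key, seen in entry["fit_seen_ids"].items():
            overlap = val & set(seen)
            if overlap:
                raise AssertionError(
                    f"leakage in repetition {entry['repetition']} fold {entry['fold']} "
                    f"({key}): {sorted(overlap)[:5]}"
                )
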