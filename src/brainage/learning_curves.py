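"""Bootstrap learning curves: training-set size versus MAE, against chance level.

Training samples are drawn with replacement from the cohort in an age- and
sex-balanced design: each size step adds one man and one woman per integer
age (54 subjects for the 27 ages of the default 47-73 range, up to 20 each,
i.e. 1,080).  A balanced validation set (default 40 per age, 20 per sex —
1,080 subjects) is held out, disjoint from every bootstrap training pool,
and the full independent site is scored as well.  Confidence intervals are
Efron percentile intervals over the bootstrap replicates.

Chance level follows the uniform-SD convention: always predicting the mean
of a uniform age distribution is assigned an expected error of
``range/sqrt(12)`` (7.5 years for ages 47-73).  Note this is the SD of the
uniform distribution; the exact mean absolute deviation from the mean of a
uniform variable is ``range/4`` (6.5 years here) — the package keeps the
uniform-SD convention for comparability and documents the discrepancy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, ParameterError
from .evaluation import (
    CVPlan,
    ModelSpec,
    _base_kind,
    _fit_fold_blocks,
    _fit_one_model,
    _resolve_cohorts,
    mae,
)
from .preprocessing import PCAConfig, normalise_by_tiv

__all__ = [
    "SizeGrid",
    "LearningCurve",
    "chance_level_mae",
    "percentile_ci",
    "bootstrap_curve",
]


def chance_level_mae(age_min: float, age_max: float) -> float:
    """Chance-level MAE of predicting the mean age, uniform-SD convention.

    ``(age_max - age_min) / sqrt(12)``; 7.5 years for the default 47-73 range.
    """
    if age_max <= age_min:
        raise ParameterError("age_max must exceed age_min")
    return (age_max - age_min) / np.sqrt(12.0)


def uniform_mean_absolute_deviation(age_min: float, age_max: float) -> float:
    """Exact mean |age - mean age| of a continuous uniform: range/4.

    Kept alongside :func:`chance_level_mae` to make the convention's
    discrepancy explicit (6.5 vs 7.5 years on 47-73).
    """
    if age_max <= age_min:
        raise ParameterError("age_max must exceed age_min")
    return (age_max - age_min) / 4.0


def percentile_ci(samples: np.ndarray, level: float = 95.0) -> tuple[float, float]:
    """Efron percentile bootstrap interval (2.5/97.5 percentiles at 95%)."""
    samples = np.asarray(samples, float)
    if samples.size < 2:
        raise ParameterError("percentile CI needs at least 2 samples")
    lo = (100.0 - level) / 2.0
    lo_v, hi_v = np.percentile(samples, [lo, 100.0 - lo])
    return float(lo_v), float(hi_v)


@dataclass(frozen=True)
class SizeGrid:
    """Balanced bootstrap design over training-set sizes.

    ``per_age_per_sex`` lists the subjects drawn per (age, sex) cell at each
    step; with 27 integer ages the default 1..20 yields total sizes
    54, 108, ..., 1080.  The validation set holds
    ``validation_per_age_per_sex`` subjects per cell (default 20 -> 1,080).
    """

    per_age_per_sex: tuple = tuple(range(1, 21))
    n_bootstrap: int = 200
    validation_per_age_per_sex: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.per_age_per_sex) == 0 or min(self.per_age_per_sex) < 1:
            raise ParameterError("per_age_per_sex must be positive counts")
        if self.n_bootstrap < 2:
            raise ParameterError("need at least 2 bootstrap replicates")

    def total_sizes(self, n_ages: int) -> list[int]:
        return [2 * n_ages * c for c in self.per_age_per_sex]

    def validation_size(self, n_ages: int) -> int:
        return 2 * n_ages * self.validation_per_age_per_sex


@dataclass(eq=False)
class LearningCurve:
    """Bootstrap MAE distributions per (model, size, split) with percentile CIs."""

    table: pd.DataFrame  # model, size, split, mean, ci_lo, ci_hi, n_replicates
    chance_level: float
    replicates: pd.DataFrame  # model, size, split, replicate, mae
    audit: list = None  # per draw: size, replicate, train_idx, validation_idx

    def above_chance_size(self, model: str, split: str = "validation") -> int | None:
        """Smallest size whose CI upper bound lies below chance, else None."""
        sub = self.table[(self.table["model"] == model) & (self.table["split"] == split)]
        ok = sub[sub["ci_hi"] < self.chance_level].sort_values("size")
        return int(ok["size"].iloc[0]) if len(ok) else None

    def plot(self, path=None):
        """Figure-1-style panel grid: MAE vs size per model, chance as a dotted line."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        models = list(dict.fromkeys(self.table["model"]))
        fig, axes = plt.subplots(
            1, len(models), figsize=(4 * len(models), 3.2), squeeze=False, sharey=True
        )
        colors = {"train": "tab:red", "validation": "tab:green", "site2": "tab:blue"}
        for ax, m in zip(axes[0], models):
            sub = self.table[self.table["model"] == m]
            for split, g in sub.groupby("split"):
                g = g.sort_values("size")
                c = colors.get(split, None)
                ax.plot(g["size"], g["mean"], label=split, color=c)
                ax.fill_between(g["size"], g["ci_lo"], g["ci_hi"], alpha=0.25, color=c)
            ax.axhline(self.chance_level, ls=":", color="black", label="chance")
            ax.set_title(m)
            ax.set_xlabel("training set size")
        axes[0][0].set_ylabel("MAE (years)")
        axes[0][-1].legend(fontsize=8)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


def _cell_indices(cohort: Cohort) -> dict[tuple[int, str], np.ndarray]:
    cells: dict[tuple[int, str], np.ndarray] = {}
    ages, sexes = cohort.ages, cohort.sex
    for a in np.unique(ages):
        for s in ("M", "F"):
            cells[(int(a), s)] = np.flatnonzero((ages == a) & (sexes == s))
    return cells


def bootstrap_curve(
    cohorts,
    models: list[ModelSpec],
    grid: SizeGrid = SizeGrid(),
    site2_cohorts=None,
    plan: CVPlan = CVPlan(),
    pca_config: PCAConfig = PCAConfig(),
) -> LearningCurve:
    """Bootstrap MAE against training-set size for every model.

    For each size and replicate a balanced training sample is drawn with
    replacement from the non-validation pool, each model is refitted (SVR
    including its nested C search), and MAE is scored on the training sample,
    the disjoint balanced validation set, and (optionally) the full
    independent site.  PCA-based models are only run at sizes exceeding the
    number of components.
    """
    cohorts = _resolve_cohorts(cohorts)
    any_cohort = next(iter(cohorts.values()))
    ages_grid = np.unique(any_cohort.ages)
    n_ages = ages_grid.size
    rng = np.random.default_rng(grid.seed)

    cells = _cell_indices(any_cohort)
    v = grid.validation_per_age_per_sex
    val_idx, pools = [], {}
    for cell, idx in cells.items():
        if idx.size < v + 1:
            raise ParameterError(
                f"cohort cannot supply {v} validation subjects plus a training pool "
                f"for age/sex cell {cell} (has {idx.size})"
            )
        perm = rng.permutation(idx)
        val_idx.append(perm[:v])
        pools[cell] = perm[v:]
    val_idx = np.sort(np.concatenate(val_idx))

    region = cohorts.get("region")
    region_norm = normalise_by_tiv(region) if region is not None else None
    voxel = cohorts.get("voxel")
    needs_gram = any(s.representation == "voxel" for s in models)

    if site2_cohorts is not None and isinstance(site2_cohorts, Cohort):
        site2_cohorts = {site2_cohorts.feature_kind: site2_cohorts}

    chance = chance_level_mae(float(ages_grid.min()), float(ages_grid.max()))
    rep_rows = []
    audit = []
    y = any_cohort.ages.astype(float)
    ids = any_cohort.ids

    for c_per_cell in grid.per_age_per_sex:
        size = 2 * n_ages * c_per_cell
        eligible = [
            s
            for s in models
            if not (s.representation == "voxel_pca" and size <= pca_config.n_components)
        ]
        if not eligible:
            continue
        for b in range(grid.n_bootstrap):
            tr = np.concatenate(
                [rng.choice(pools[cell], size=c_per_cell, replace=True) for cell in cells]
            )
            audit.append(
                {"size": size, "replicate": b, "train_idx": tr, "validation_idx": val_idx}
            )
            gram = None
            if needs_gram:
                xv = voxel.features[tr]
                gram = xv @ xv.T
            blocks = _fit_fold_blocks(
                eligible, region_norm, voxel, None, tr, ids, pca_config, None
            ) if not needs_gram else _fit_fold_blocks_boot(
                eligible, region_norm, voxel, gram, tr, ids, pca_config
            )
            for j, spec in enumerate(eligible):
                seed = int(
                    np.random.SeedSequence((grid.seed, int(size), b, j)).generate_state(1)[0]
                    % (2**31 - 1)
                )
                tm, _ = _fit_one_model(spec, blocks, y, any_cohort.ages, tr, plan, pca_config, seed)
                tm.representation = spec.representation
                base = cohorts[_base_kind(spec.representation)]
                splits = {
                    "train": base.subset(tr),
                    "validation": base.subset(val_idx),
                }
                if site2_cohorts is not None:
                    splits["site2"] = site2_cohorts[_base_kind(spec.representation)]
                for split, sub in splits.items():
                    pred = tm.predict_cohort(sub)
                    rep_rows.append(
                        {
                            "model": spec.name,
                            "size": size,
                            "split": split,
                            "replicate": b,
                            "mae": mae(sub.ages.astype(float), pred),
                        }
                    )

    replicates = pd.DataFrame.from_records(rep_rows)
    agg_rows = []
    for (m, size, split), g in replicates.groupby(["model", "size", "split"]):
        vals = g["mae"].to_numpy(float)
        lo, hi = percentile_ci(vals)
        agg_rows.append(
            {
                "model": m,
                "size": int(size),
                "split": split,
                "mean": float(vals.mean()),
                "ci_lo": lo,
                "ci_hi": hi,
                "n_replicates": vals.size,
            }
        )
    table = pd.DataFrame.from_records(agg_rows).sort_values(["model", "split", "size"])
    return LearningCurve(
        table=table.reset_index(drop=True),
        chance_level=chance,
        replicates=replicates,
        audit=audit,
    )


def _fit_fold_blocks_boot(models, region_norm, voxel, gram_tr, tr, ids, pca_config):
    """Variant of the CV block builder for bootstrap samples: the Gram matrix
    is computed on the (possibly duplicated) training rows directly."""
    blocks = _fit_fold_blocks(
        [s for s in models if s.representation != "voxel"],
        region_norm,
        voxel,
        None,
        tr,
        ids,
        pca_config,
        None,
    )
    if any(s.representation == "voxel" for s in models):
        blocks["voxel"] = {"X_tr": voxel.features[tr], "gram_tr": gram_tr}
    return blocks
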