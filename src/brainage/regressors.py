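"""The three linear brain-age regressors: SVR, EM relevance vector regression, GPR.

SVR and GPR delegate to scikit-learn estimators with the benchmark's fixed
settings (linear / dot-product kernels only).  Relevance vector regression is
implemented here from the expectation-maximisation update rules of sparse
Bayesian regression:

    Sigma = (beta Phi' Phi + diag(alpha))^-1
    mu    = beta Sigma Phi' y
    gamma_i = 1 - alpha_i Sigma_ii
    alpha_i <- gamma_i / mu_i^2
    beta    <- (N - sum_i gamma_i) / ||y - Phi mu||^2

Basis functions whose precision ``alpha_i`` exceeds the pruning threshold are
removed; the training points behind the surviving basis functions are the
relevance vectors.  No bias basis function is added; instead the target is
centred internally (an unpenalised intercept at the training mean age),
without which a linear-kernel basis over column-centred features cannot
represent the ~60-year mean target and the EM collapses.

All three models are linear in the features, so kernel fits are collapsed to
primal weights after training (``w = X_sv' dual``) — predictions are a dot
product with the stored weight vector regardless of how the model was fitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import DotProduct
from sklearn.svm import SVR as _SklearnSVR
from sklearn.svm import LinearSVR as _SklearnLinearSVR

from .cohort import Cohort, ParameterError
from .preprocessing import DataError, IncrementalPCABasis, RobustScaler

__all__ = [
    "SVRConfig",
    "RVRConfig",
    "GPRConfig",
    "RVRFit",
    "TrainedModel",
    "DegenerateRVRError",
    "NumericError",
    "fit_svr",
    "fit_rvr",
    "fit_gpr",
    "rvr_posterior",
    "predict_with_uncertainty",
]

# full-scale convention: fewer than 600 relevance vectors out of ~9,432
# training subjects marked a fit as underfitted; stored as a fraction so
# desk-scale runs behave comparably
UNDERFIT_FRACTION = 600.0 / 9432.0


class DegenerateRVRError(RuntimeError):
    """Every basis function was pruned; carries the mean-age fallback."""

    def __init__(self, fallback_mean: float, n_train: int):
        super().__init__(
            "all RVR basis functions were pruned; falling back to the "
            f"training mean age ({fallback_mean:.2f})"
        )
        self.fallback_mean = float(fallback_mean)
        self.n_train = int(n_train)


class NumericError(RuntimeError):
    """Numerical failure (e.g. Gram matrix not positive definite)."""


@dataclass(frozen=True)
class SVRConfig:
    """Linear epsilon-insensitive SVR settings (C selected by nested CV)."""

    C: float = 1.0
    epsilon: float = 0.0
    tol: float = 1e-4
    max_iter: int = 1000
    kernel: str = "linear"  # "linear" | "precomputed"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ParameterError("C must be positive")
        if self.epsilon < 0:
            raise ParameterError("epsilon must be non-negative")
        if self.kernel not in ("linear", "precomputed"):
            raise ParameterError("SVR kernel must be 'linear' or 'precomputed'")


@dataclass(frozen=True)
class RVRConfig:
    """EM relevance vector regression settings."""

    kernel: str = "linear"  # "linear" | "precomputed"
    alpha_prune_threshold: float = 1e9
    max_iter: int = 5000
    tol: float = 1e-3  # convergence on max |delta log alpha|
    alpha_init: float = 1e-6
    beta_init: float | None = None  # default 1/var(y)
    underfit_fraction: float = UNDERFIT_FRACTION

    def __post_init__(self) -> None:
        if self.alpha_prune_threshold <= 0:
            raise ParameterError("alpha_prune_threshold must be positive")
        if self.max_iter < 1:
            raise ParameterError("max_iter must be >= 1")
        if self.kernel not in ("linear", "precomputed"):
            raise ParameterError("RVR kernel must be 'linear' or 'precomputed'")


@dataclass(frozen=True)
class GPRConfig:
    """GPR with a dot-product kernel and small observation jitter."""

    sigma_0: float = 1.0
    optimise: bool = True  # maximise log marginal likelihood over sigma_0
    jitter: float = 1e-10
    n_restarts: int = 0  # additional optimiser restarts beyond the single run
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter <= 0:
            raise ParameterError("jitter must be positive")


@dataclass(eq=False)
class RVRFit:
    """Posterior summary of one EM-RVR fit."""

    mu: np.ndarray  # posterior mean weights over surviving basis functions
    sigma: np.ndarray  # posterior covariance over surviving basis functions
    active: np.ndarray  # indices of surviving basis functions / relevance vectors
    alpha: np.ndarray  # final precisions for surviving basis functions
    beta: float  # final noise precision
    n_train: int
    n_iter: int
    converged: bool
    rv_history: list[int] = field(default_factory=list)
    underfit_fraction: float = UNDERFIT_FRACTION

    @property
    def n_relevance_vectors(self) -> int:
        return int(self.active.size)

    @property
    def underfit_threshold(self) -> int:
        """Absolute relevance-vector count below which the fit is flagged."""
        return int(np.ceil(self.underfit_fraction * self.n_train))

    @property
    def underfit(self) -> bool:
        return self.n_relevance_vectors < self.underfit_threshold


@dataclass(eq=False)
class TrainedModel:
    """A fitted regressor bundled with its training-time transforms.

    ``predict_cohort`` applies exactly the transforms fitted on the training
    fold (TIV normalisation flag, PCA basis, robust scaler) and then either
    the collapsed linear weights or the wrapped estimator, so held-out and
    independent-site predictions reuse training statistics only.
    """

    kind: str  # "svr" | "rvr" | "gpr"
    representation: str = "region"  # "region" | "voxel" | "voxel_pca"
    weights: np.ndarray | None = None
    intercept: float = 0.0
    estimator: object | None = None
    scaler: RobustScaler | None = None
    pca: IncrementalPCABasis | None = None
    tiv_normalised: bool = False
    metadata: dict = field(default_factory=dict)

    def transform(self, X: np.ndarray, tiv: np.ndarray | None = None) -> np.ndarray:
        if self.tiv_normalised:
            if tiv is None:
                raise DataError("model was trained on TIV-normalised volumes; TIV required")
            X = X / np.asarray(tiv, float)[:, None]
        if self.pca is not None:
            X = self.pca.transform(X)
        if self.scaler is not None:
            X = self.scaler.transform(X)
        return X

    def predict(self, X: np.ndarray, tiv: np.ndarray | None = None) -> np.ndarray:
        X = self.transform(np.asarray(X, float), tiv)
        if self.estimator is not None:
            return np.asarray(self.estimator.predict(X), float)
        if self.weights is None:
            return np.full(X.shape[0], self.intercept)
        if X.shape[1] != self.weights.shape[0]:
            raise DataError(
                f"feature dimension {X.shape[1]} does not match the "
                f"{self.weights.shape[0]} features seen at fit time"
            )
        return X @ self.weights + self.intercept

    def predict_cohort(self, cohort: Cohort) -> np.ndarray:
        tiv = cohort.tiv if self.tiv_normalised else None
        return self.predict(cohort.features, tiv=tiv)


def _check_finite(*arrays) -> None:
    for a in arrays:
        if not np.all(np.isfinite(a)):
            raise DataError("non-finite values in model inputs")


# ---------------------------------------------------------------------------
# SVR


def fit_svr(
    X: np.ndarray,
    y: np.ndarray,
    config: SVRConfig = SVRConfig(),
    features: np.ndarray | None = None,
) -> TrainedModel:
    """Fit linear epsilon-insensitive SVR.

    ``kernel="linear"`` expects a subjects x features matrix and uses
    LinearSVR.  ``kernel="precomputed"`` expects the training Gram matrix in
    ``X`` plus the raw ``features`` it was computed from, fits kernel SVR and
    collapses the dual solution to primal weights.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    _check_finite(X, y)
    if config.kernel == "linear":
        est = _SklearnLinearSVR(
            C=config.C,
            epsilon=config.epsilon,
            tol=config.tol,
            max_iter=config.max_iter,
            loss="epsilon_insensitive",
            random_state=config.seed,
        )
        est.fit(X, y)
        return TrainedModel(
            kind="svr",
            weights=est.coef_.ravel().copy(),
            intercept=float(np.atleast_1d(est.intercept_)[0]),
            metadata={"C": config.C, "n_iter": int(np.max(est.n_iter_))},
        )
    if features is None:
        raise ParameterError("precomputed-kernel SVR needs the raw training features")
    features = np.asarray(features, float)
    est = _SklearnSVR(
        kernel="precomputed",
        C=config.C,
        epsilon=config.epsilon,
        tol=config.tol,
        max_iter=config.max_iter if config.max_iter > 0 else -1,
    )
    est.fit(X, y)
    w = features[est.support_].T @ est.dual_coef_.ravel()
    return TrainedModel(
        kind="svr",
        weights=w,
        intercept=float(est.intercept_[0]),
        metadata={"C": config.C, "n_support": int(est.support_.size)},
    )


def svr_objective(
    X: np.ndarray, y: np.ndarray, w: np.ndarray, b: float, C: float, epsilon: float = 0.0
) -> float:
    """Primal epsilon-insensitive objective 0.5||w||^2 + C sum max(0, |r|-eps)."""
    r = np.abs(y - X @ w - b) - epsilon
    return 0.5 * float(w @ w) + C * float(np.clip(r, 0.0, None).sum())


# ---------------------------------------------------------------------------
# RVR


def rvr_posterior(
    Phi: np.ndarray, y: np.ndarray, alpha: np.ndarray, beta: float
) -> tuple[np.ndarray, np.ndarray]:
    """Weight posterior (mu, Sigma) at fixed precisions.

    At fixed ``alpha`` and ``beta`` the posterior mean coincides with ridge
    regression with per-weight penalty ``alpha_i / beta``.
    """
    a = beta * (Phi.T @ Phi) + np.diag(alpha)
    try:
        c, low = cho_factor(a)
    except LinAlgError as err:  # pragma: no cover - pathological inputs
        raise NumericError(f"posterior precision matrix not positive definite: {err}") from err
    sigma = cho_solve((c, low), np.eye(a.shape[0]))
    mu = beta * (sigma @ (Phi.T @ y))
    return mu, sigma


def fit_rvr(
    X: np.ndarray,
    y: np.ndarray,
    config: RVRConfig = RVRConfig(),
    features: np.ndarray | None = None,
) -> tuple[RVRFit, TrainedModel]:
    """Fit EM relevance vector regression with a linear or precomputed kernel.

    ``kernel="linear"``: ``X`` is subjects x features and the basis is the
    linear kernel ``Phi = X X'``.  ``kernel="precomputed"``: ``X`` is the
    training Gram matrix and ``features`` are the raw vectors behind it.
    Returns the posterior fit plus a deployable :class:`TrainedModel` whose
    weights live in the raw feature space.

    Both target and features are centred internally (equivalent to an
    unpenalised intercept at the training mean); without this, a no-bias
    linear-kernel basis cannot represent the ~60-year mean target and the EM
    collapses.  A precomputed Gram matrix is double-centred accordingly.  The
    mean is restored at prediction time, and it is also the natural fallback
    when every basis function is pruned.

    Raises :class:`DegenerateRVRError` (carrying the training-mean fallback)
    when every basis function is pruned.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    _check_finite(X, y)
    y_mean = float(y.mean())
    y = y - y_mean
    n = y.size
    if config.kernel == "linear":
        raw_feats = X
    else:
        if features is None:
            raise ParameterError("precomputed-kernel RVR needs the raw training features")
        raw_feats = np.asarray(features, float)
    x_mean = raw_feats.mean(axis=0)
    feats = raw_feats - x_mean
    if config.kernel == "linear":
        phi_full = feats @ feats.T
    else:
        if X.shape != (n, n):
            raise ParameterError("RVR basis matrix must be n_train x n_train")
        # double-centre the supplied Gram matrix: for K = X X' this equals
        # the Gram matrix of the column-centred features
        row = X.mean(axis=0)
        phi_full = X - row[None, :] - row[:, None] + row.mean()
    if phi_full.shape != (n, n):
        raise ParameterError("RVR basis matrix must be n_train x n_train")

    var_y = float(np.var(y))
    if var_y < 1e-12:
        # constant target: nothing beyond the mean to model
        raise DegenerateRVRError(fallback_mean=y_mean, n_train=n)
    active = np.arange(n)
    alpha = np.full(n, config.alpha_init, float)
    beta = config.beta_init if config.beta_init is not None else 1.0 / var_y

    gram_full = phi_full.T @ phi_full  # (Phi' Phi) for column subsetting
    phity_full = phi_full.T @ y

    mu = np.zeros(0)
    sigma = np.zeros((0, 0))
    rv_history: list[int] = []
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        a = beta * gram_full[np.ix_(active, active)] + np.diag(alpha)
        try:
            c, low = cho_factor(a)
        except LinAlgError:
            # ill-conditioned at extreme beta; retry with a tiny diagonal ridge
            try:
                c, low = cho_factor(a + 1e-8 * np.trace(a) / a.shape[0] * np.eye(a.shape[0]))
            except LinAlgError as err:
                raise NumericError(
                    f"RVR posterior precision matrix not positive definite: {err}"
                ) from err
        sigma = cho_solve((c, low), np.eye(active.size))
        mu = beta * (sigma @ phity_full[active])

        gamma = 1.0 - alpha * np.diag(sigma)
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha_new = np.where(mu**2 > 0, gamma / mu**2, np.inf)
        alpha_new = np.clip(alpha_new, 1e-12, np.inf)
        resid = y - phi_full[:, active] @ mu
        denom = max(float(resid @ resid), 1e-12)
        beta = min(max(n - float(gamma.sum()), 1e-6) / denom, 1e12)

        keep = alpha_new < config.alpha_prune_threshold
        delta = np.abs(np.log(alpha_new[keep]) - np.log(alpha[keep])) if keep.any() else np.array([])
        alpha = alpha_new[keep]
        active = active[keep]
        mu = mu[keep]
        sigma = sigma[np.ix_(keep, keep)]
        rv_history.append(int(active.size))
        if active.size == 0:
            raise DegenerateRVRError(fallback_mean=y_mean, n_train=n)
        if delta.size and float(delta.max()) < config.tol:
            converged = True
            break

    fit = RVRFit(
        mu=mu,
        sigma=sigma,
        active=active,
        alpha=alpha,
        beta=float(beta),
        n_train=n,
        n_iter=it,
        converged=converged,
        rv_history=rv_history,
        underfit_fraction=config.underfit_fraction,
    )
    # collapse to primal weights: basis j is k(x, x_j) = (x - xbar).(x_j - xbar),
    # so f(x) = (x - xbar).(Xc_active' mu) + ybar = x.w + (ybar - xbar.w)
    w = feats[active].T @ mu
    model = TrainedModel(
        kind="rvr",
        weights=w,
        intercept=y_mean - float(x_mean @ w),
        metadata={
            "n_relevance_vectors": fit.n_relevance_vectors,
            "underfit": fit.underfit,
            "beta": fit.beta,
            "n_iter": fit.n_iter,
            "converged": fit.converged,
        },
    )
    return fit, model


# ---------------------------------------------------------------------------
# GPR


def fit_gpr(
    X: np.ndarray, y: np.ndarray, config: GPRConfig = GPRConfig()
) -> TrainedModel:
    """Fit GPR with a dot-product kernel by maximising the log marginal likelihood."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    _check_finite(X, y)
    kernel = DotProduct(sigma_0=config.sigma_0)
    if not config.optimise:
        kernel = DotProduct(sigma_0=config.sigma_0, sigma_0_bounds="fixed")
    est = GaussianProcessRegressor(
        kernel=kernel,
        alpha=config.jitter,
        optimizer="fmin_l_bfgs_b" if config.optimise else None,
        n_restarts_optimizer=config.n_restarts if config.optimise else 0,
        normalize_y=False,
        random_state=config.seed,
    )
    try:
        est.fit(X, y)
    except np.linalg.LinAlgError as err:
        raise NumericError(
            f"Gram matrix not positive definite ({err}); increase the jitter"
        ) from err
    return TrainedModel(kind="gpr", estimator=est, metadata={"kernel": str(est.kernel_)})


def predict_with_uncertainty(
    model: TrainedModel, X: np.ndarray, tiv: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior predictive mean and variance (GPR models only)."""
    if model.kind != "gpr" or model.estimator is None:
        raise ParameterError("predictive uncertainty is available for GPR models only")
    Z = model.transform(np.asarray(X, float), tiv)
    mean, std = model.estimator.predict(Z, return_std=True)
    return np.asarray(mean, float), np.asarray(std, float) ** 2
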