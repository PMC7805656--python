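"""Stage-1 learners and hyperparameter tuning.

The general regression neural network (GRNN) is implemented here from its
defining equation — a Gaussian-kernel (Nadaraya–Watson) weighted average of
the stored training outputs,

    yhat(x) = sum_i Y_i exp(-D_i^2 / 2 sigma^2) / sum_i exp(-D_i^2 / 2 sigma^2),

with D_i^2 the squared Euclidean distance to training pattern i and a
single spread parameter sigma.  Training is memorization: one pattern unit
per training sample.  Prediction is stabilized by subtracting the largest
exponent per query before exponentiation, which also yields the natural
fallback — when every other kernel underflows the prediction collapses to
the nearest pattern unit's output.

nu-SVR (RBF kernel, one model per output axis) and random-forest regression
(ensemble mean over trees) are standard learners and are provided by
scikit-learn behind thin per-axis wrappers.  Hyperparameters for all three
are selected by exhaustive grid search under shuffled 10-fold cross
validation on the training data, scored by mean validation MSE averaged
over output dimensions; ties break toward the smoothest model (largest
sigma, smallest C, fewest trees).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics.pairwise import euclidean_distances
from sklearn.svm import NuSVR

from .errors import ConfigError, DataError

ALGORITHMS = ("grnn", "svr", "rf")


# ---------------------------------------------------------------------------
# GRNN
# ---------------------------------------------------------------------------


class GRNN:
    """General regression neural network with spread ``sigma``.

    Handles any output dimensionality: with a shared sigma the multi-output
    prediction equals running one single-output GRNN per axis, since the
    kernel weights depend only on the inputs.
    """

    def __init__(self, sigma: float):
        if not (sigma > 0):
            raise ConfigError(f"GRNN spread must be positive, got {sigma}")
        self.sigma = float(sigma)
        self.X_: np.ndarray | None = None
        self.Y_: np.ndarray | None = None

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "GRNN":
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if X.ndim != 2 or X.shape[0] == 0:
            raise DataError("GRNN requires a nonempty 2-D training matrix")
        if Y.shape[0] != X.shape[0]:
            raise DataError("X and Y must have the same number of rows")
        self.X_ = X
        self.Y_ = Y
        return self

    @property
    def n_pattern_units(self) -> int:
        if self.X_ is None:
            raise DataError("GRNN is not fitted")
        return self.X_.shape[0]

    def predict(self, X: np.ndarray, chunk: int = 1024) -> np.ndarray:
        """Kernel-weighted average of stored outputs, per query row."""
        if self.X_ is None or self.Y_ is None:
            raise DataError("GRNN is not fitted")
        Xq = np.asarray(X, dtype=float)
        if Xq.ndim != 2 or Xq.shape[1] != self.X_.shape[1]:
            raise DataError(
                f"query dimensionality {Xq.shape} does not match training "
                f"({self.X_.shape[1]} features)"
            )
        out = np.empty((Xq.shape[0], self.Y_.shape[1]))
        inv = 1.0 / (2.0 * self.sigma**2)
        for start in range(0, Xq.shape[0], chunk):
            block = Xq[start : start + chunk]
            d2 = euclidean_distances(block, self.X_, squared=True)
            np.maximum(d2, 0.0, out=d2)
            e = -d2 * inv
            e -= e.max(axis=1, keepdims=True)  # stabilize: max exponent -> 0
            w = np.exp(e)
            den = w.sum(axis=1, keepdims=True)  # >= 1 after stabilization
            out[start : start + chunk] = (w @ self.Y_) / den
        return out


def grnn_fit(X: np.ndarray, Y: np.ndarray, sigma: float) -> GRNN:
    return GRNN(sigma).fit(X, Y)


def grnn_predict(model: GRNN, X: np.ndarray) -> np.ndarray:
    return model.predict(X)


# ---------------------------------------------------------------------------
# SVR / RF wrappers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SVRConfig:
    """nu-SVR with RBF kernel k(x,y) = exp(-||x-y||^2 / 2 sigma_rbf^2).

    ``sigma_rbf`` may be the string ``"scale"`` to defer to the usual
    variance-based bandwidth heuristic.
    """

    nu: float = 0.5
    c: float = 10.0
    sigma_rbf: float | str = "scale"

    def __post_init__(self) -> None:
        if not (0 < self.nu <= 1):
            raise ConfigError("nu must lie in (0, 1]")
        if self.c <= 0:
            raise ConfigError("C must be positive")
        if isinstance(self.sigma_rbf, str):
            if self.sigma_rbf != "scale":
                raise ConfigError(f"unknown sigma_rbf {self.sigma_rbf!r}")
        elif self.sigma_rbf <= 0:
            raise ConfigError("sigma_rbf must be positive")

    @property
    def gamma(self) -> float | str:
        if isinstance(self.sigma_rbf, str):
            return "scale"
        return 1.0 / (2.0 * self.sigma_rbf**2)


@dataclass(frozen=True)
class RFConfig:
    """Random forest: ensemble mean of ``n_trees`` regression trees."""

    n_trees: int = 100
    max_depth: int | None = None
    max_features: float | str = 1.0 / 3.0
    min_samples_leaf: int = 1

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ConfigError("number of trees must be >= 1")


class PerAxisRegressor:
    """Train one single-output estimator per output column."""

    def __init__(self, factory):
        self._factory = factory
        self.models_: list[Any] = []

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "PerAxisRegressor":
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        self.models_ = []
        for j in range(Y.shape[1]):
            m = self._factory()
            m.fit(X, Y[:, j])
            self.models_.append(m)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.column_stack([m.predict(X) for m in self.models_])


def _check_finite(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise DataError("features must be finite")
    return X


def svr_fit_predict(
    cfg: SVRConfig, X: np.ndarray, y_column: np.ndarray, Xq: np.ndarray
) -> np.ndarray:
    """Fit a single-axis nu-SVR and predict the query rows."""
    X, Xq = _check_finite(X), _check_finite(Xq)
    m = NuSVR(nu=cfg.nu, C=cfg.c, gamma=cfg.gamma)
    m.fit(X, np.asarray(y_column, dtype=float).ravel())
    return m.predict(Xq)


def rf_fit_predict(
    cfg: RFConfig, X: np.ndarray, y_column: np.ndarray, Xq: np.ndarray, seed: int = 0
) -> np.ndarray:
    """Fit a single-axis random forest and predict the query rows."""
    X, Xq = _check_finite(X), _check_finite(Xq)
    m = _rf_estimator(cfg, seed)
    m.fit(X, np.asarray(y_column, dtype=float).ravel())
    return m.predict(Xq)


def _rf_estimator(cfg: RFConfig, seed: int) -> RandomForestRegressor:
    return RandomForestRegressor(
        n_estimators=cfg.n_trees,
        max_depth=cfg.max_depth,
        max_features=cfg.max_features,
        min_samples_leaf=cfg.min_samples_leaf,
        random_state=seed,
        n_jobs=1,
    )


def make_regressor(algorithm: str, params: Mapping[str, Any], seed: int = 0):
    """Instantiate a fit/predict model for one algorithm + parameter set."""
    if algorithm == "grnn":
        return GRNN(sigma=params["sigma"])
    if algorithm == "svr":
        cfg = SVRConfig(**params)
        return PerAxisRegressor(lambda: NuSVR(nu=cfg.nu, C=cfg.c, gamma=cfg.gamma))
    if algorithm == "rf":
        cfg = RFConfig(**params)
        return PerAxisRegressor(lambda: _rf_estimator(cfg, seed))
    raise ConfigError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")


# ---------------------------------------------------------------------------
# Grid-search tuning under 10-fold cross validation
# ---------------------------------------------------------------------------


def default_grids() -> dict[str, list[dict]]:
    """Config-exposed default grids (none are prescribed by the protocol)."""
    return {
        "grnn": [{"sigma": s} for s in np.logspace(-2, 0, 10)],
        "svr": [
            {"nu": nu, "c": c, "sigma_rbf": s}
            for nu in (0.25, 0.5, 0.75)
            for c in (1.0, 10.0, 100.0)
            for s in (0.1, 1.0, 10.0)
        ],
        "rf": [
            {"n_trees": b, "max_depth": d}
            for b in (50, 100, 200)
            for d in (10, 20, None)
        ],
    }


@dataclass
class TuningPlan:
    """Grid and fold layout for hyperparameter search."""

    grids: dict[str, list[dict]] = field(default_factory=default_grids)
    n_folds: int = 10
    seed: int = 0
    blocked: bool = False  # contiguous folds for temporal-leakage studies

    def grid_for(self, algorithm: str) -> list[dict]:
        grid = self.grids.get(algorithm, [])
        if not grid:
            raise ConfigError(f"empty tuning grid for {algorithm!r}")
        return grid


def fold_indices(n: int, k: int, seed: int, blocked: bool = False) -> list[np.ndarray]:
    """Partition [0, n) into k validation folds (shuffled by default)."""
    if n < k:
        raise DataError(f"cannot make {k} folds from {n} samples")
    idx = np.arange(n)
    if not blocked:
        rng = np.random.default_rng(seed)
        rng.shuffle(idx)
    return [np.sort(part) for part in np.array_split(idx, k)]


def _smoothness_key(algorithm: str, params: Mapping[str, Any]) -> tuple:
    # smaller key = smoother model; used only for tie-breaking
    if algorithm == "grnn":
        return (-params["sigma"],)
    if algorithm == "svr":
        return (params["c"], params["nu"])
    if algorithm == "rf":
        depth = params.get("max_depth")
        return (params["n_trees"], np.inf if depth is None else depth)
    return ()


def tune(
    plan: TuningPlan,
    algorithm: str,
    X: np.ndarray,
    Y: np.ndarray,
    seed: int = 0,
) -> dict:
    """Exhaustive grid search; returns the parameters with the lowest mean
    validation MSE over the folds (ties to the smoothest model)."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    grid = plan.grid_for(algorithm)
    if len(grid) == 1:
        return dict(grid[0])
    if X.shape[0] < plan.n_folds:
        raise DataError(f"need >= {plan.n_folds} samples to tune")
    folds = fold_indices(X.shape[0], plan.n_folds, plan.seed, plan.blocked)
    if algorithm == "grnn":
        scores = _score_grnn_grid(grid, folds, X, Y)
    else:
        scores = _score_generic_grid(algorithm, grid, folds, X, Y, seed)
    finite = np.isfinite(scores)
    if not finite.any():
        raise DataError("all grid points failed during tuning")
    best_score = scores[finite].min()
    # scores equal to float precision count as ties; break toward smoothness
    tied = [
        i
        for i in range(len(grid))
        if finite[i] and scores[i] <= best_score + 1e-9 * max(abs(best_score), 1e-12)
    ]
    best = min(tied, key=lambda i: _smoothness_key(algorithm, grid[i]))
    return dict(grid[best])


def _score_grnn_grid(
    grid: Sequence[Mapping], folds: Sequence[np.ndarray], X: np.ndarray, Y: np.ndarray
) -> np.ndarray:
    """Score all sigmas reusing one distance matrix per fold."""
    scores = np.zeros(len(grid))
    n = X.shape[0]
    for val in folds:
        train = np.setdiff1d(np.arange(n), val)
        d2 = euclidean_distances(X[val], X[train], squared=True)
        np.maximum(d2, 0.0, out=d2)
        for gi, params in enumerate(grid):
            e = -d2 / (2.0 * params["sigma"] ** 2)
            e -= e.max(axis=1, keepdims=True)
            w = np.exp(e)
            pred = (w @ Y[train]) / w.sum(axis=1, keepdims=True)
            scores[gi] += np.mean((pred - Y[val]) ** 2)
    return scores / len(folds)


def _score_generic_grid(
    algorithm: str,
    grid: Sequence[Mapping],
    folds: Sequence[np.ndarray],
    X: np.ndarray,
    Y: np.ndarray,
    seed: int,
) -> np.ndarray:
    scores = np.zeros(len(grid))
    n = X.shape[0]
    for val in folds:
        train = np.setdiff1d(np.arange(n), val)
        for gi, params in enumerate(grid):
            try:
                m = make_regressor(algorithm, params, seed=seed)
                m.fit(X[train], Y[train])
                pred = m.predict(X[val])
                scores[gi] += np.mean((pred - Y[val]) ** 2)
            except (ValueError, FloatingPointError):
                scores[gi] += np.inf
    return scores / len(folds)
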