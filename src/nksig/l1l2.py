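"""Sparse linear classification with combined l1 + l2 penalties.

The model is f(x) = beta . x + b with the class given by sign(f).  Training
minimizes

    (1/n) ||y - X beta - b||^2  +  tau ||beta||_1  +  mu ||beta||_2^2

over standardized features (per-feature z-scores computed from the training
data only; the intercept is unpenalized, so with centered columns it equals
mean(y)).  The l1 term drives exact zeros (variable selection); the small l2
term keeps groups of correlated variables together instead of picking one
arbitrarily.  tau = 0 is exactly ridge / regularized least squares, the
estimator reused by the Monte-Carlo validation stage.

The solver is FISTA (accelerated proximal gradient with soft-thresholding)
with backtracking line search and a function-value restart, which makes the
recorded objective non-increasing.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "LinearModel",
    "fit_l1l2",
    "fit_rls",
    "predict",
    "regularization_path",
    "tau_max",
    "auto_tau_grid",
]


@dataclass
class LinearModel:
    """A fitted sparse (or ridge) linear classifier on standardized inputs."""

    feature_names: list[str]
    beta: np.ndarray          # weights on z-scored features
    intercept: float
    mean: np.ndarray          # training means, one per feature
    sd: np.ndarray            # training standard deviations, all > 0
    tau: float
    mu: float
    loss: str = "square"
    converged: bool = True
    n_iter: int = 0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        d = len(self.feature_names)
        if not (self.beta.shape == self.mean.shape == self.sd.shape == (d,)):
            raise ValueError("beta/mean/sd must all have one entry per feature")
        if (self.sd <= 0).any():
            raise ValueError("standardization sd must be positive")

    @property
    def selected(self) -> list[str]:
        return [f for f, b in zip(self.feature_names, self.beta) if b != 0.0]

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}"
            )
        Z = (X - self.mean) / self.sd
        return Z @ self.beta + self.intercept

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "feature_names": self.feature_names,
            "beta": self.beta.tolist(),
            "intercept": self.intercept,
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "tau": self.tau,
            "mu": self.mu,
            "loss": self.loss,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "LinearModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)
        return cls(
            feature_names=doc["feature_names"],
            beta=np.array(doc["beta"]),
            intercept=doc["intercept"],
            mean=np.array(doc["mean"]),
            sd=np.array(doc["sd"]),
            tau=doc["tau"],
            mu=doc["mu"],
            loss=doc.get("loss", "square"),
            converged=doc.get("converged", True),
            n_iter=doc.get("n_iter", 0),
        )


def predict(model: LinearModel, X: np.ndarray) -> np.ndarray:
    """Class labels in {-1, +1}; a decision value of exactly 0 maps to +1."""
    f = model.decision_function(X)
    return np.where(f >= 0.0, 1.0, -1.0)


def _standardize(X: np.ndarray):
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    return mean, sd, keep


def _soft(v: np.ndarray, t: float) -> np.ndarray:
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    classes = np.unique(y)
    if not np.all(np.isin(classes, (-1.0, 1.0))):
        raise ValueError("labels must be coded -1 / +1")
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    return y


def fit_l1l2(
    X: np.ndarray,
    y: np.ndarray,
    tau: float,
    mu: float,
    feature_names: list[str] | None = None,
    tol: float = 1e-6,
    max_iter: int = 10_000,
    beta0: np.ndarray | None = None,
) -> LinearModel:
    """Fit the l1+l2 penalized square-loss model by FISTA.

    Convergence requires both the relative objective change and the relative
    iterate change to drop below ``tol`` (the objective alone cannot resolve
    parameter accuracy near the optimum in floating point); otherwise the
    best iterate is returned with ``converged=False`` and a warning.
    ``beta0`` warm-starts the solver (used along regularization paths).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional (samples x features)")
    y = _check_labels(y)
    n, d = X.shape
    if len(y) != n:
        raise ValueError("X and y disagree on the number of samples")
    if tau < 0 or mu < 0:
        raise ValueError("penalties tau and mu must be non-negative")
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(d)]

    mean, sd, keep = _standardize(X)
    sd_safe = np.where(keep, sd, 1.0)
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} constant feature(s) receive zero weight")
    Z = (X - mean) / sd_safe
    Z[:, ~keep] = 0.0
    yc = y - y.mean()

    def objective(b):
        r = yc - Z @ b
        return (r @ r) / n + tau * np.abs(b).sum() + mu * (b @ b)

    # Lipschitz constant of the smooth part: 2 sigma_max(Z)^2 / n + 2 mu
    if n and d:
        gram_small = Z @ Z.T if n <= d else Z.T @ Z
        smax2 = float(np.linalg.eigvalsh(gram_small)[-1]) if gram_small.size else 0.0
    else:
        smax2 = 0.0
    L = 2.0 * smax2 / n + 2.0 * mu if n else 1.0
    L = max(L, 1e-12)

    b = np.zeros(d) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    v = b.copy()          # extrapolated point
    t_mom = 1.0
    obj = objective(b)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        r = yc - Z @ v
        grad = -2.0 * (Z.T @ r) / n + 2.0 * mu * v
        step = 1.0 / L
        # backtracking on the smooth part's quadratic upper bound
        fv = (r @ r) / n + mu * (v @ v)
        while True:
            b_new = _soft(v - step * grad, tau * step)
            diff = b_new - v
            r_new = yc - Z @ b_new
            f_new = (r_new @ r_new) / n + mu * (b_new @ b_new)
            bound = fv + grad @ diff + (diff @ diff) / (2 * step)
            if f_new <= bound + 1e-12 or step < 1e-16:
                break
            step *= 0.5
        obj_new = objective(b_new)
        if obj_new > obj:            # monotone restart: reject the momentum
            v = b.copy()
            t_mom = 1.0
            r = yc - Z @ v
            grad = -2.0 * (Z.T @ r) / n + 2.0 * mu * v
            b_new = _soft(v - grad / L, tau / L)
            obj_new = objective(b_new)
            if obj_new > obj:        # plain step cannot improve further
                converged = True
                break
        t_new = (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2)) / 2.0
        v = b_new + ((t_mom - 1.0) / t_new) * (b_new - b)
        rel_obj = abs(obj - obj_new) / max(abs(obj), 1e-12)
        rel_step = (np.abs(b_new - b).max()
                    / max(np.abs(b_new).max(), 1e-12))
        b, obj, t_mom = b_new, obj_new, t_new
        if rel_obj < tol and rel_step < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"fit_l1l2 did not converge in {max_iter} iterations "
            f"(last objective {obj:.6g})"
        )
    # polish: plain proximal-gradient steps are monotone and contract to the
    # unique fixed point; a short tail sharpens the iterate beyond what the
    # objective-change test can resolve in floating point
    for _ in range(200):
        grad = -2.0 * (Z.T @ (yc - Z @ b)) / n + 2.0 * mu * b
        b_new = _soft(b - grad / L, tau / L)
        delta = np.abs(b_new - b).max()
        b = b_new
        if delta < 1e-14 * max(1.0, np.abs(b).max()):
            break
    b[~keep] = 0.0
    return LinearModel(
        feature_names=list(feature_names),
        beta=b,
        intercept=float(y.mean()),
        mean=mean,
        sd=sd_safe,
        tau=tau,
        mu=mu,
        converged=converged,
        n_iter=it,
    )


def fit_rls(
    X: np.ndarray,
    y: np.ndarray,
    mu: float,
    feature_names: list[str] | None = None,
) -> LinearModel:
    """Regularized least squares (ridge) in closed form: tau = 0 exactly.

    Solves (Z'Z + n mu I) beta = Z' (y - mean(y)) on standardized features,
    via the dual when d > n.
    """
    X = np.asarray(X, dtype=float)
    y = _check_labels(y)
    n, d = X.shape
    if mu <= 0:
        raise ValueError("fit_rls requires mu > 0 (the system may be singular)")
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(d)]
    mean, sd, keep = _standardize(X)
    sd_safe = np.where(keep, sd, 1.0)
    Z = (X - mean) / sd_safe
    Z[:, ~keep] = 0.0
    yc = y - y.mean()
    if d <= n:
        A = Z.T @ Z + n * mu * np.eye(d)
        beta = np.linalg.solve(A, Z.T @ yc)
    else:
        A = Z @ Z.T + n * mu * np.eye(n)
        beta = Z.T @ np.linalg.solve(A, yc)
    beta[~keep] = 0.0
    return LinearModel(
        feature_names=list(feature_names),
        beta=beta,
        intercept=float(y.mean()),
        mean=mean,
        sd=sd_safe,
        tau=0.0,
        mu=mu,
    )


def tau_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest tau for which the l1l2 solution is identically zero.

    At beta = 0 the subgradient condition gives tau >= 2 |Z' yc|_inf / n.
    """
    X = np.asarray(X, dtype=float)
    y = _check_labels(y)
    n = X.shape[0]
    mean, sd, keep = _standardize(X)
    Z = (X - mean) / np.where(keep, sd, 1.0)
    Z[:, ~keep] = 0.0
    yc = y - y.mean()
    return float(2.0 * np.abs(Z.T @ yc).max() / n)


def auto_tau_grid(X, y, n_points: int = 10, ratio: float = 0.05) -> np.ndarray:
    """Descending geometric grid from tau_max down to ratio * tau_max.

    The default floor (tau_max/20) stays above the regime where, at n << d,
    the lasso active set explodes to near-saturation and its size becomes
    erratically data-dependent; selected-set sizes along the default grid
    are then stable across learning sets.
    """
    tmax = tau_max(X, y)
    if tmax == 0:
        return np.zeros(n_points)
    return tmax * np.logspace(0, np.log10(ratio), n_points)


def regularization_path(
    X: np.ndarray,
    y: np.ndarray,
    tau_grid,
    mu: float,
    feature_names: list[str] | None = None,
    **fit_kwargs,
) -> list[LinearModel]:
    """Warm-started l1l2 fits along a descending tau grid."""
    tau_grid = np.asarray(tau_grid, dtype=float)
    if tau_grid.size == 0:
        raise ValueError("tau_grid is empty")
    if np.any(np.diff(tau_grid) > 0):
        raise ValueError("tau_grid must be non-increasing")
    models = []
    beta0 = None
    for tau in tau_grid:
        m = fit_l1l2(X, y, tau=float(tau), mu=mu,
                     feature_names=feature_names, beta0=beta0, **fit_kwargs)
        beta0 = m.beta
        models.append(m)
    return models
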