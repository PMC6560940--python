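"""Kernel ridge regression with derivative prediction and model selection.

An :class:`Interpolant` is a kernel expansion ``g(t) = sum_i b_i k(t, t_i)``
whose coefficients solve the regularized least-squares problem

    sum_i (g(t_i) - y_i)^2 + lam * b' K b

with closed-form solution ``b = (K + lam I)^(-1) y``.  The regularization
weight is selected by cross validation on a grid; kernel hyperparameters are
optimized on the log scale with a multi-start quasi-Newton routine against
the same held-out objective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from .kernels import JITTER, KernelSpec, gram_matrix, kernel_matrix

__all__ = [
    "Interpolant",
    "RidgeFactorizationError",
    "fit_ridge",
    "predict",
    "predict_dt",
    "predict_d2t",
    "ridge_loss",
    "select_lambda_cv",
    "optimize_kernel_hyperparams",
    "HyperparamSearch",
    "fit_state_interpolant",
    "default_lambda_grid",
]


class RidgeFactorizationError(RuntimeError):
    """Raised when (K + lam I) cannot be factorized."""


@dataclass
class Interpolant:
    """A fitted kernel expansion with its training context."""

    kernel: KernelSpec
    train_times: np.ndarray
    coefficients: np.ndarray
    lam: float

    def __post_init__(self) -> None:
        self.train_times = np.asarray(self.train_times, dtype=float).ravel()
        self.coefficients = np.asarray(self.coefficients, dtype=float).ravel()
        if self.train_times.shape != self.coefficients.shape:
            raise ValueError(
                "coefficient vector and training-time vector must have equal length"
            )
        if self.lam < 0:
            raise ValueError("lam must be nonnegative")

    def __call__(self, t):
        return predict(self, t)

    def dt(self, t):
        return predict_dt(self, t)

    def d2t(self, t):
        return predict_d2t(self, t)


def _solve_regularized(K: np.ndarray, lam: float, y: np.ndarray) -> np.ndarray:
    """Solve (K + lam I) b = y, escalating diagonal jitter only if needed.

    The jitter ladder starts at zero so that the exact closed form is
    returned whenever the plain system is well posed.
    """
    n = K.shape[0]
    eye = np.eye(n)
    last_exc: Exception | None = None
    for jitter in (0.0, JITTER, 1e-6, 1e-4):
        A = K + (lam + jitter) * eye
        try:
            c, low = linalg.cho_factor(A)
            return linalg.cho_solve((c, low), y)
        except linalg.LinAlgError as exc:  # not positive definite at this jitter
            last_exc = exc
    raise RidgeFactorizationError(
        "could not factorize (K + lam I); increase lam or add jitter "
        "(duplicated abscissa values with lam=0 are a common cause)"
    ) from last_exc


def fit_ridge(times, y, kernel: KernelSpec, lam: float) -> Interpolant:
    """Fit coefficients ``b = (K + lam I)^(-1) y``."""
    times = np.asarray(times, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if times.size != y.size:
        raise ValueError("times and y must have equal length")
    if times.size < 2:
        raise ValueError("need at least two observations")
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    K = gram_matrix(kernel, times)
    b = _solve_regularized(K, lam, y)
    return Interpolant(kernel=kernel, train_times=times, coefficients=b, lam=float(lam))


def predict(interp: Interpolant, t):
    out = kernel_matrix(interp.kernel, np.atleast_1d(t), interp.train_times) @ interp.coefficients
    return out if np.ndim(t) else float(out[0])


def predict_dt(interp: Interpolant, t):
    out = (
        kernel_matrix(interp.kernel, np.atleast_1d(t), interp.train_times, deriv=1)
        @ interp.coefficients
    )
    return out if np.ndim(t) else float(out[0])


def predict_d2t(interp: Interpolant, t):
    out = (
        kernel_matrix(interp.kernel, np.atleast_1d(t), interp.train_times, deriv=2)
        @ interp.coefficients
    )
    return out if np.ndim(t) else float(out[0])


def ridge_loss(times, y, kernel: KernelSpec, lam: float, coefficients) -> float:
    """Regularized training loss ``sum (g(t_i)-y_i)^2 + lam b' K b``."""
    times = np.asarray(times, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    b = np.asarray(coefficients, dtype=float).ravel()
    K = gram_matrix(kernel, times)
    resid = K @ b - y
    return float(resid @ resid + lam * b @ K @ b)


def default_lambda_grid(num: int = 12, low: float = 1e-6, high: float = 1e2) -> np.ndarray:
    return np.logspace(np.log10(low), np.log10(high), num)


def _fold_indices(n: int, folds: int, scheme: str, seed: int | None) -> list[np.ndarray]:
    idx = np.arange(n)
    if scheme == "random":
        idx = np.random.default_rng(seed).permutation(n)
    elif scheme != "blocks":
        raise ValueError(f"unknown CV scheme {scheme!r}")
    return [f for f in np.array_split(idx, folds) if f.size]


def _cv_error(times, y, kernel: KernelSpec, lam: float, folds_idx) -> float:
    total = 0.0
    count = 0
    for held in folds_idx:
        mask = np.ones(times.size, dtype=bool)
        mask[held] = False
        if mask.sum() < 2:
            raise ValueError("fold leaves fewer than two training points")
        try:
            interp = fit_ridge(times[mask], y[mask], kernel, lam)
        except RidgeFactorizationError:
            return np.inf
        pred = predict(interp, times[held])
        total += float(np.sum((pred - y[held]) ** 2))
        count += held.size
    return total / count


def select_lambda_cv(
    times,
    y,
    kernel: KernelSpec,
    lam_grid,
    folds: int,
    scheme: str = "blocks",
    seed: int | None = None,
) -> float:
    """Grid value minimizing mean held-out squared error (ties -> first on grid)."""
    times = np.asarray(times, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    lam_grid = np.asarray(lam_grid, dtype=float).ravel()
    if lam_grid.size == 0:
        raise ValueError("lam_grid must be nonempty")
    n = times.size
    if not 2 <= folds <= n:
        raise ValueError(f"folds must lie in [2, n={n}], got {folds}")
    folds_idx = _fold_indices(n, folds, scheme, seed)
    errors = [_cv_error(times, y, kernel, lam, folds_idx) for lam in lam_grid]
    return float(lam_grid[int(np.argmin(errors))])


@dataclass
class HyperparamSearch:
    """Trace of a multi-start hyperparameter optimization."""

    spec: KernelSpec
    objective: float
    start_specs: list[KernelSpec] = field(default_factory=list)
    start_objectives: list[float] = field(default_factory=list)
    converged: bool = True


def optimize_kernel_hyperparams(
    times,
    y,
    kernel_family: str,
    lam: float,
    bounds: dict[str, tuple[float, float]],
    n_starts: int = 5,
    folds: int = 10,
    scheme: str = "blocks",
    seed: int = 0,
    return_info: bool = False,
):
    """Optimize kernel hyperparameters against held-out CV error.

    The search runs on the log scale inside ``bounds`` with ``n_starts``
    seeded initializations (the first start sits at the lower-bound corner,
    which also resolves degenerate flat objectives deterministically).
    """
    times = np.asarray(times, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    names = sorted(bounds)
    lo = np.array([bounds[p][0] for p in names], dtype=float)
    hi = np.array([bounds[p][1] for p in names], dtype=float)
    if np.any(lo <= 0) or np.any(~np.isfinite(hi)) or np.any(hi < lo):
        raise ValueError("bounds must be finite, positive, and ordered")
    folds = min(folds, times.size)
    folds_idx = _fold_indices(times.size, folds, scheme, seed)

    def objective(log_phi: np.ndarray) -> float:
        spec = KernelSpec(kernel_family, dict(zip(names, np.exp(log_phi))))
        val = _cv_error(times, y, spec, lam, folds_idx)
        return val if np.isfinite(val) else 1e12

    log_lo, log_hi = np.log(lo), np.log(hi)
    rng = np.random.default_rng(seed)
    starts = [log_lo.copy()]
    starts += [rng.uniform(log_lo, log_hi) for _ in range(max(0, n_starts - 1))]

    best_x, best_val = None, np.inf
    start_specs, start_objs = [], []
    any_converged = False
    for x0 in starts:
        res = optimize.minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=list(zip(log_lo, log_hi)),
            options={"maxiter": 200},
        )
        any_converged = any_converged or bool(res.success)
        start_specs.append(KernelSpec(kernel_family, dict(zip(names, np.exp(x0)))))
        start_objs.append(float(objective(x0)))
        if res.fun < best_val - 1e-15:
            best_val, best_x = float(res.fun), res.x
    if best_x is None:  # flat objective: keep the first start
        best_x, best_val = starts[0], start_objs[0]
    if not any_converged:
        warnings.warn(
            "hyperparameter optimizer did not report convergence from any start; "
            "returning best iterate",
            RuntimeWarning,
        )
    spec = KernelSpec(kernel_family, dict(zip(names, np.exp(best_x))))
    if return_info:
        return HyperparamSearch(
            spec=spec,
            objective=best_val,
            start_specs=start_specs,
            start_objectives=start_objs,
            converged=any_converged,
        )
    return spec


def _default_bounds(times: np.ndarray, y: np.ndarray, family: str) -> dict:
    span = float(times.max() - times.min())
    scale = float(np.std(y))
    scale = scale if scale > 0 else 1.0
    if family == "rbf":
        return {
            "lengthscale": (span / 50.0, span),
            "amplitude": (0.05 * scale, 20.0 * scale),
        }
    if family == "mlp":
        return {"weight_variance": (1e-3, 1e2), "bias_variance": (1e-3, 1e2)}
    raise ValueError(f"no default hyperparameter bounds for family {family!r}")


def fit_state_interpolant(
    times,
    y,
    family: str = "rbf",
    lam_grid=None,
    folds: int = 10,
    bounds: dict | None = None,
    n_starts: int = 5,
    rounds: int = 2,
    scheme: str = "blocks",
    seed: int = 0,
) -> Interpolant:
    """Full single-state smoothing pass: alternate lam grid-CV and
    hyperparameter optimization for ``rounds`` rounds, then fit."""
    times = np.asarray(times, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if lam_grid is None:
        lam_grid = default_lambda_grid()
    if bounds is None:
        bounds = _default_bounds(times, y, family)
    folds = min(folds, times.size)
    span = float(times.max() - times.min())
    scale = float(np.std(y)) or 1.0
    if family == "rbf":
        init = {"lengthscale": span / 8.0, "amplitude": scale}
    else:
        init = {"weight_variance": 1.0, "bias_variance": 1.0}
    spec = KernelSpec(family, {k: float(np.clip(v, *bounds[k])) for k, v in init.items()})
    lam = float(lam_grid[0])
    for _ in range(rounds):
        lam = select_lambda_cv(times, y, spec, lam_grid, folds, scheme=scheme, seed=seed)
        spec = optimize_kernel_hyperparams(
            times, y, family, lam, bounds, n_starts=n_starts, folds=folds,
            scheme=scheme, seed=seed,
        )
    lam = select_lambda_cv(times, y, spec, lam_grid, folds, scheme=scheme, seed=seed)
    return fit_ridge(times, y, spec, lam)
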