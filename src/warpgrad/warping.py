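"""Bijective time warps that homogenize a signal's intrinsic length scales.

Stage 1 learns, per observed state, a strictly increasing map

    w(t) = sum_j exp(b_j) * S(t - t_j, l),    S(z, l) = 1 / (1 + exp(-l z))

by minimizing a penalty that rewards the warped signal for behaving like a
regular oscillation (proportionality between the signal and its second
derivative in warped time), plus an endpoint anchor that discourages
degenerate maps.  Stage 2 smooths the fitted knot pairs (t_i, w(t_i)) with
kernel ridge regression under an MLP kernel, whose analytic derivative
supplies the chain-rule factor w'(t) used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import expit

from .kernels import KernelSpec, kernel_matrix
from .ridge import fit_ridge

__all__ = [
    "SigmoidWarp",
    "SmoothedWarp",
    "WarpObjectiveConfig",
    "DegenerateWarpError",
    "MonotonicityError",
    "warp_eval",
    "warp_derivative",
    "warp_second_derivative",
    "q_curvature_at_knots",
    "warp_objective",
    "warp_objective_terms",
    "fit_warp",
    "smooth_warp",
]


class DegenerateWarpError(RuntimeError):
    """The warp derivative collapsed below the usable threshold."""


class MonotonicityError(RuntimeError):
    """A smoothed warp failed the monotonicity check."""


@dataclass
class SigmoidWarp:
    """Sum of positively weighted logistic steps; strictly increasing by construction."""

    log_weights: np.ndarray
    steepness: float
    centers: np.ndarray

    def __post_init__(self) -> None:
        self.log_weights = np.asarray(self.log_weights, dtype=float).ravel()
        self.centers = np.asarray(self.centers, dtype=float).ravel()
        if self.log_weights.shape != self.centers.shape:
            raise ValueError("log_weights and centers must have equal length")
        if self.steepness <= 0:
            raise ValueError("steepness must be positive")

    def __call__(self, t):
        return warp_eval(self, t)


@dataclass
class SmoothedWarp:
    """MLP-kernel ridge smoothing of a fitted warp, with analytic derivative."""

    coefficients: np.ndarray
    mlp_kernel: KernelSpec
    lam: float
    train_times: np.ndarray

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float).ravel()
        self.train_times = np.asarray(self.train_times, dtype=float).ravel()
        if self.coefficients.shape != self.train_times.shape:
            raise ValueError("coefficients and train_times must have equal length")

    def __call__(self, t):
        return warp_eval(self, t)


@dataclass
class WarpObjectiveConfig:
    """Settings of the warp loss.

    ``lambda_w_bounds`` restricts the admissible angular frequency of the
    target oscillation; ``lambda_t`` weights the endpoint anchor; ``T0, T1``
    are the original endpoints.  ``center_signal`` subtracts the knot mean of
    the interpolant from the oscillation term, making the loss invariant to
    a constant offset of the signal.
    """

    T0: float
    T1: float
    lambda_w_bounds: tuple[float, float] = field(default=None)  # type: ignore[assignment]
    lambda_t: float = field(default=None)  # type: ignore[assignment]
    center_signal: bool = True
    n_knots: int = 0  # informs the default frequency upper bound

    def __post_init__(self) -> None:
        if not self.T1 > self.T0:
            raise ValueError("need T1 > T0")
        span = self.T1 - self.T0
        if self.lambda_w_bounds is None:
            n = max(self.n_knots, 4)
            self.lambda_w_bounds = (2.0 * np.pi / span, np.pi * n / span)
        lo, hi = self.lambda_w_bounds
        if not (0 < lo < hi):
            raise ValueError("lambda_w_bounds must satisfy 0 < lo < hi")
        if self.lambda_t is None:
            self.lambda_t = 1e3
        if self.lambda_t <= 0:
            raise ValueError("lambda_t must be positive")


# -- evaluation ------------------------------------------------------------------

def _sigmoid_parts(warp: SigmoidWarp, t: np.ndarray):
    z = warp.steepness * (t[..., None] - warp.centers)
    s = expit(z)
    w = np.exp(warp.log_weights)
    return s, w


def warp_eval(warp, t):
    """Evaluate the warp ``t -> t~``; scalar in, scalar out."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if isinstance(warp, SigmoidWarp):
        s, wts = _sigmoid_parts(warp, t_arr)
        out = s @ wts
    elif isinstance(warp, SmoothedWarp):
        out = kernel_matrix(warp.mlp_kernel, t_arr, warp.train_times) @ warp.coefficients
    elif callable(warp):  # duck-typed warp (testing hooks, frozen warps)
        out = np.atleast_1d(np.asarray(warp(t_arr), dtype=float))
    else:
        raise TypeError(f"unsupported warp type {type(warp).__name__}")
    return out if np.ndim(t) else float(out[0])


def warp_derivative(warp, t):
    """Analytic ``dw/dt``; positive by construction for :class:`SigmoidWarp`."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if isinstance(warp, SigmoidWarp):
        s, wts = _sigmoid_parts(warp, t_arr)
        out = (warp.steepness * s * (1.0 - s)) @ wts
    elif isinstance(warp, SmoothedWarp):
        out = (
            kernel_matrix(warp.mlp_kernel, t_arr, warp.train_times, deriv=1)
            @ warp.coefficients
        )
        if np.any(out <= 0):
            raise MonotonicityError(
                "smoothed warp has non-positive derivative at a requested point"
            )
    elif hasattr(warp, "derivative"):
        out = np.atleast_1d(np.asarray(warp.derivative(t_arr), dtype=float))
    else:
        raise TypeError(f"unsupported warp type {type(warp).__name__}")
    return out if np.ndim(t) else float(out[0])


def warp_second_derivative(warp, t):
    """Analytic ``d2w/dt2``."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if isinstance(warp, SigmoidWarp):
        s, wts = _sigmoid_parts(warp, t_arr)
        out = (warp.steepness**2 * s * (1.0 - s) * (1.0 - 2.0 * s)) @ wts
    elif isinstance(warp, SmoothedWarp):
        out = (
            kernel_matrix(warp.mlp_kernel, t_arr, warp.train_times, deriv=2)
            @ warp.coefficients
        )
    elif hasattr(warp, "second_derivative"):
        out = np.atleast_1d(np.asarray(warp.second_derivative(t_arr), dtype=float))
    else:
        raise TypeError(f"unsupported warp type {type(warp).__name__}")
    return out if np.ndim(t) else float(out[0])


# -- warp objective --------------------------------------------------------------

def q_curvature_at_knots(g, warp, times) -> np.ndarray:
    """Second derivative of the warped-domain signal q at the warped knots.

    q is defined implicitly by g = q o w; inverting the chain rule gives
    q' = g'/w' and q'' = (g'' - q' w'') / w'^2, all evaluated at the knots.
    ``g`` may be any object exposing ``__call__``, ``dt`` and ``d2t``.
    """
    times = np.asarray(times, dtype=float).ravel()
    w1 = np.atleast_1d(warp_derivative(warp, times))
    if np.any(w1 < 1e-10):
        raise DegenerateWarpError("warp derivative below 1e-10 at a knot")
    w2 = np.atleast_1d(warp_second_derivative(warp, times))
    g1 = np.atleast_1d(g.dt(times))
    g2 = np.atleast_1d(g.d2t(times))
    q1 = g1 / w1
    return (g2 - q1 * w2) / (w1 * w1)


def warp_objective_terms(
    g, warp, lam_w: float, cfg: WarpObjectiveConfig, times
) -> tuple[float, float]:
    """(oscillation term, endpoint term) of the warp loss."""
    times = np.asarray(times, dtype=float).ravel()
    qdd = q_curvature_at_knots(g, warp, times)
    qvals = np.atleast_1d(g(times))
    if cfg.center_signal:
        qvals = qvals - qvals.mean()
    resid = qdd + lam_w * lam_w * qvals
    data_term = float(resid @ resid)
    w_t0 = warp_eval(warp, cfg.T0)
    w_t1 = warp_eval(warp, cfg.T1)
    end_term = float(cfg.lambda_t * ((w_t1 - cfg.T1) ** 2 + (w_t0 - cfg.T0) ** 2))
    return data_term, end_term


def warp_objective(g, warp, lam_w: float, cfg: WarpObjectiveConfig, times) -> float:
    data_term, end_term = warp_objective_terms(g, warp, lam_w, cfg, times)
    return data_term + end_term


# -- stage-1 fitting -------------------------------------------------------------

def _lam_w_from_u(u: float, lo: float, hi: float) -> float:
    return lo + (hi - lo) * expit(u)


def fit_warp(
    g,
    times,
    cfg: WarpObjectiveConfig,
    seed: int = 0,
    n_restarts: int = 5,
    maxiter: int = 200,
    steepness_factors: tuple[float, float] = (0.5, 4.0),
    weight_log_halfwidth: float = 1.0,
) -> tuple[SigmoidWarp, float]:
    """Minimize the warp loss over (log-weights, steepness, frequency).

    The frequency lam_w is driven through a rescaled sigmoid so it stays in
    ``cfg.lambda_w_bounds``.  The steepness is box-constrained to
    ``steepness_factors`` divided by the knot spacing: an unconstrained
    steepness admits a degenerate staircase warp whose derivative spikes at
    exactly the knots, zeroing the curvature term without homogenizing
    anything.  Restart 0 is the identity-approximating initialization
    (equal weights spanning [T0, T1]); the remaining restarts are seeded
    perturbations.  The returned loss never exceeds the loss at restart
    0's initialization.
    """
    times = np.asarray(times, dtype=float).ravel()
    n = times.size
    lo, hi = cfg.lambda_w_bounds
    span = cfg.T1 - cfg.T0
    spacing = span / n

    def unpack(p: np.ndarray) -> tuple[SigmoidWarp, float]:
        warp = SigmoidWarp(
            log_weights=p[:n], steepness=float(np.exp(p[n])), centers=times
        )
        return warp, _lam_w_from_u(float(p[n + 1]), lo, hi)

    def objective(p: np.ndarray) -> float:
        try:
            warp, lam_w = unpack(p)
            val = warp_objective(g, warp, lam_w, cfg, times)
        except (DegenerateWarpError, FloatingPointError, OverflowError):
            return 1e12
        return val if np.isfinite(val) else 1e12

    b0 = np.log(spacing)
    p0 = np.concatenate([np.full(n, b0), [np.log(2.0 / spacing)], [0.0]])
    box = (
        [(b0 - weight_log_halfwidth, b0 + weight_log_halfwidth)] * n
        + [(np.log(steepness_factors[0] / spacing), np.log(steepness_factors[1] / spacing))]
        + [(-10.0, 10.0)]
    )
    box_lo = np.array([b[0] for b in box])
    box_hi = np.array([b[1] for b in box])
    rng = np.random.default_rng(seed)

    def with_best_frequency(p: np.ndarray) -> np.ndarray:
        # coarse grid over the frequency channel; the joint landscape is
        # highly multimodal in lam_w, so anchor each start near its best mode
        p = p.copy()
        u_grid = np.linspace(-4.0, 4.0, 17)
        vals = []
        for u in u_grid:
            p[n + 1] = u
            vals.append(objective(p))
        p[n + 1] = u_grid[int(np.argmin(vals))]
        return p

    starts = [with_best_frequency(np.clip(p0, box_lo, box_hi))]
    for _ in range(max(0, n_restarts - 1)):
        pert = p0.copy()
        pert[:n] += rng.normal(scale=0.3, size=n)
        pert[n] += rng.normal(scale=0.3)
        starts.append(with_best_frequency(np.clip(pert, box_lo, box_hi)))

    best_p, best_val = None, np.inf
    for x0 in starts:
        try:
            res = optimize.minimize(
                objective, x0, method="L-BFGS-B", bounds=box, options={"maxiter": maxiter}
            )
        except Exception:  # pragma: no cover - defensive
            continue
        val = float(res.fun)
        if val < best_val:
            best_val, best_p = val, res.x
    if best_p is None:
        raise RuntimeError(
            f"all {len(starts)} warp optimizer restarts failed (initial loss "
            f"{objective(starts[0]):.3g})"
        )
    warp, lam_w = unpack(best_p)
    return warp, lam_w


# -- stage-2 smoothing -----------------------------------------------------------

def smooth_warp(
    times,
    warped_times,
    mlp_kernel: KernelSpec | None = None,
    seed: int = 0,
    lam_grid=None,
    grid_points: int = 1000,
    domain: tuple[float, float] | None = None,
) -> SmoothedWarp:
    """Ridge-smooth the knot pairs (t_i, t~_i) with an MLP kernel.

    The regularization weight is chosen by leave-one-out cross validation;
    among the grid values, candidates are tried in LOO order and the first
    whose fit is strictly increasing on a dense grid wins.
    """
    times = np.asarray(times, dtype=float).ravel()
    warped_times = np.asarray(warped_times, dtype=float).ravel()
    if times.size != warped_times.size:
        raise ValueError("times and warped_times must have equal length")
    if np.any(np.diff(warped_times) <= 0):
        raise ValueError("warped_times must be strictly increasing")
    if mlp_kernel is None:
        mlp_kernel = KernelSpec.mlp(1.0, 1.0)
    if lam_grid is None:
        lam_grid = np.logspace(-8, 1, 12)
    lam_grid = np.asarray(lam_grid, dtype=float).ravel()
    if domain is None:
        domain = (float(times.min()), float(times.max()))
    dense = np.linspace(domain[0], domain[1], grid_points)

    n = times.size
    loo = []
    for lam in lam_grid:
        # exhaustive leave-one-out refits (n is small here)
        total = 0.0
        ok = True
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            try:
                fit = fit_ridge(times[mask], warped_times[mask], mlp_kernel, lam)
            except Exception:
                ok = False
                break
            total += (fit(float(times[i])) - warped_times[i]) ** 2
        loo.append(total / n if ok else np.inf)
    order = np.argsort(loo)

    for j in order:
        if not np.isfinite(loo[j]):
            continue
        lam = float(lam_grid[j])
        fit = fit_ridge(times, warped_times, mlp_kernel, lam)
        cand = SmoothedWarp(
            coefficients=fit.coefficients,
            mlp_kernel=mlp_kernel,
            lam=lam,
            train_times=times,
        )
        deriv = (
            kernel_matrix(mlp_kernel, dense, times, deriv=1) @ cand.coefficients
        )
        if np.all(deriv > 0):
            return cand
    raise MonotonicityError(
        "no regularization value on the grid produced a monotone smoothed warp; "
        "extend lam_grid toward larger values"
    )
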