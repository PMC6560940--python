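"""Shared fixtures: analytic stubs, benchmark datasets, fast fit settings."""

from __future__ import annotations

import numpy as np
import pytest

from warpgrad.datasets import generate_dataset
from warpgrad.odes import ODEModel, get_model
from warpgrad.pipeline import FitConfig, WarpFitConfig

# Generation protocol used throughout: adaptive low-order RK output over one
# limit-cycle window, every 2nd solver step kept (n = 28).
LV_THETA = {"alpha": 1.0, "beta": 1.0, "gamma": 4.0, "delta": 1.0}
LV_X0 = [0.5, 1.0]
LV_SPAN = (0.0, 4.7)
LV_SOLVE = dict(n_solver_points=None, rtol=1e-3, atol=1e-6)


class AnalyticCurve:
    """Duck-typed interpolant backed by closed-form derivatives."""

    def __init__(self, f, df, d2f):
        self._f, self._df, self._d2f = f, df, d2f

    def __call__(self, t):
        return self._f(np.asarray(t, dtype=float))

    def dt(self, t):
        return self._df(np.asarray(t, dtype=float))

    def d2t(self, t):
        return self._d2f(np.asarray(t, dtype=float))


class LinearWarp:
    """Duck-typed affine warp ``w(t) = a t + b`` with exact derivatives."""

    def __init__(self, a: float = 1.0, b: float = 0.0):
        self.a, self.b = a, b

    def __call__(self, t):
        return self.a * np.asarray(t, dtype=float) + self.b

    def derivative(self, t):
        return np.full_like(np.asarray(t, dtype=float), self.a)

    def second_derivative(self, t):
        return np.zeros_like(np.asarray(t, dtype=float))


@pytest.fixture(scope="session")
def lv_model() -> ODEModel:
    return get_model("lotka_volterra")


@pytest.fixture(scope="session")
def lv_dataset_40db(lv_model):
    """One noisy Lotka-Volterra replicate at 40 dB, n = 28."""
    return generate_dataset(
        lv_model, LV_THETA, LV_X0, LV_SPAN, snr_db=40.0, seed=7, **LV_SOLVE
    )


@pytest.fixture(scope="session")
def lv_dataset_clean(lv_model):
    """Noise-free, dense (every solver step kept)."""
    return generate_dataset(
        lv_model, LV_THETA, LV_X0, LV_SPAN, snr_db=np.inf, seed=0,
        keep_every=1, n_solver_points=None, rtol=1e-3, atol=1e-6,
    )


@pytest.fixture(scope="session")
def harmonic_model() -> ODEModel:
    """2-state linear oscillator: a constant-frequency (homogeneous) system."""
    return ODEModel(
        name="harmonic",
        state_names=("x1", "x2"),
        param_names=("omega",),
        rhs=lambda x, t, th: np.array([th[0] * x[1], -th[0] * x[0]]),
        param_bounds=((1e-2, 1e1),),
    )


@pytest.fixture(scope="session")
def fast_cfg() -> FitConfig:
    """Reduced-effort settings for pipeline tests (keeps the suite quick)."""
    return FitConfig(
        lam_grid=tuple(np.logspace(-6, 1, 8)),
        folds=5,
        hyper_starts=3,
        rounds=1,
        theta_starts=3,
        warp=WarpFitConfig(n_restarts=3, maxiter=120),
    )
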