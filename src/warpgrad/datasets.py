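"""Synthetic benchmark datasets: solve, downsample, add SNR-controlled noise.

The generation protocol is: integrate the model on a configured output grid,
keep every ``keep_every``-th point, and corrupt each state independently
with iid Gaussian noise whose standard deviation is set from that state's
clean signal at the requested signal-to-noise ratio in dB.  Every draw is
reproducible from an integer seed; replicate suites derive per-replicate
seeds deterministically from a single base seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .odes import ODEModel, Trajectory, solve

__all__ = [
    "Dataset",
    "snr_to_sigma",
    "downsample_solver_output",
    "generate_dataset",
    "generate_replicate_suite",
]


@dataclass
class Dataset:
    """Noisy observations with provenance.

    ``truth`` holds the generating parameters, initial state and the clean
    (noise-free) signal at the kept abscissa values, when known.
    """

    times: np.ndarray
    observations: np.ndarray  # (n, r)
    state_names: tuple[str, ...]
    snr_db: float
    seed: int
    model_name: str
    truth: dict | None = field(default=None)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).ravel()
        self.observations = np.atleast_2d(np.asarray(self.observations, dtype=float))
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.observations.shape[0] != self.times.size:
            raise ValueError("observations must have one row per time point")
        if self.observations.shape[1] != len(self.state_names):
            raise ValueError("observations must have one column per state")

    @property
    def n(self) -> int:
        return self.times.size

    # -- plain-text round trip ---------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        frame = pd.DataFrame(
            {"time": self.times, **{s: self.observations[:, j] for j, s in enumerate(self.state_names)}}
        )
        frame.to_csv(path, index=False)
        sidecar = {
            "model_name": self.model_name,
            "state_names": list(self.state_names),
            "snr_db": None if np.isinf(self.snr_db) else self.snr_db,
            "seed": self.seed,
        }
        if self.truth is not None:
            sidecar["truth"] = {
                "theta": self.truth.get("theta"),
                "x0": list(map(float, self.truth.get("x0", []))),
                "clean": np.asarray(self.truth["clean"]).tolist()
                if "clean" in self.truth
                else None,
                "span": list(map(float, self.truth.get("span", []))),
            }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "Dataset":
        path = Path(path)
        frame = pd.read_csv(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        state_names = tuple(meta["state_names"])
        truth = meta.get("truth")
        if truth is not None and truth.get("clean") is not None:
            truth = dict(truth)
            truth["clean"] = np.asarray(truth["clean"], dtype=float)
        snr = meta.get("snr_db")
        return cls(
            times=frame["time"].to_numpy(),
            observations=frame[list(state_names)].to_numpy(),
            state_names=state_names,
            snr_db=np.inf if snr is None else float(snr),
            seed=int(meta["seed"]),
            model_name=meta["model_name"],
            truth=truth,
        )


def snr_to_sigma(signal, snr_db: float, center: bool = True) -> float:
    """Noise sd for a target SNR in dB: ``sigma = rms(signal) * 10^(-snr/20)``.

    With ``center=True`` (default) the RMS is taken about the signal mean,
    making the SNR invariant to constant offsets.
    """
    signal = np.asarray(signal, dtype=float).ravel()
    rms = float(np.std(signal)) if center else float(np.sqrt(np.mean(signal**2)))
    if rms == 0.0:
        raise ValueError("signal is constant; SNR-based noise scale is undefined")
    if np.isinf(snr_db):
        return 0.0
    return rms * 10.0 ** (-snr_db / 20.0)


def downsample_solver_output(trajectory: Trajectory, keep_every: int = 2) -> Trajectory:
    """Keep indices 0, keep_every, 2*keep_every, ... of a trajectory."""
    if keep_every < 1:
        raise ValueError("keep_every must be >= 1")
    return Trajectory(
        times=trajectory.times[::keep_every], states=trajectory.states[::keep_every]
    )


def _noisify(
    clean: Trajectory,
    model: ODEModel,
    theta,
    x0,
    span,
    snr_db: float,
    seed: int,
    center: bool,
) -> Dataset:
    rng = np.random.default_rng(seed)
    obs = clean.states.copy()
    for s in range(obs.shape[1]):
        sigma = snr_to_sigma(clean.states[:, s], snr_db, center=center)
        if sigma > 0:
            obs[:, s] = obs[:, s] + rng.normal(0.0, sigma, size=obs.shape[0])
    return Dataset(
        times=clean.times,
        observations=obs,
        state_names=model.state_names,
        snr_db=snr_db,
        seed=seed,
        model_name=model.name,
        truth={
            "theta": model.theta_dict(theta),
            "x0": list(np.asarray(x0, dtype=float)),
            "clean": clean.states.copy(),
            "span": [float(span[0]), float(span[1])],
        },
    )


def generate_dataset(
    model: ODEModel,
    theta,
    x0,
    span: tuple[float, float],
    snr_db: float,
    seed: int,
    keep_every: int = 2,
    n_solver_points: int | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-8,
    center: bool = True,
) -> Dataset:
    """Solve, downsample, add per-state Gaussian noise; reproducible from seed.

    ``n_solver_points`` fixes the solver output grid (uniform over ``span``)
    so the post-downsampling observation count is ``ceil(n_solver_points /
    keep_every)``; when omitted, the solver's own adaptive steps are used.
    """
    t_eval = (
        np.linspace(span[0], span[1], n_solver_points)
        if n_solver_points is not None
        else None
    )
    traj = solve(model, theta, x0, span, t_eval=t_eval, rtol=rtol, atol=atol)
    clean = downsample_solver_output(traj, keep_every)
    return _noisify(clean, model, theta, x0, span, snr_db, seed, center)


def _derive_seed(base_seed: int, snr_index: int, rep: int) -> int:
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(snr_index, rep))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def generate_replicate_suite(
    model: ODEModel,
    theta,
    x0,
    span: tuple[float, float],
    snr_list,
    n_reps: int,
    base_seed: int,
    keep_every: int = 2,
    n_solver_points: int | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-8,
    center: bool = True,
) -> list[Dataset]:
    """Fan a single clean solve out into ``len(snr_list) * n_reps`` noisy datasets.

    Per-dataset seeds are derived deterministically from ``base_seed`` and
    the (snr, replicate) index, so suite regeneration is byte-identical.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    t_eval = (
        np.linspace(span[0], span[1], n_solver_points)
        if n_solver_points is not None
        else None
    )
    traj = solve(model, theta, x0, span, t_eval=t_eval, rtol=rtol, atol=atol)
    clean = downsample_solver_output(traj, keep_every)
    suite = []
    for i, snr in enumerate(snr_list):
        for rep in range(n_reps):
            seed = _derive_seed(base_seed, i, rep)
            suite.append(_noisify(clean, model, theta, x0, span, float(snr), seed, center))
    return suite
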