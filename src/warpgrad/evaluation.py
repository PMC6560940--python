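"""Error metrics and paired statistical comparison of estimators.

Parameter-space error is the absolute deviation per parameter (with weakly
identifiable pairs collapsed to the error of their ratio); function-space
error is the RMS discrepancy between trajectories solved at estimated and
true parameters.  Methods are compared replicate-by-replicate with paired
Wilcoxon signed-rank tests at the 5% level, without multiple-testing
correction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import Dataset
from .odes import IntegrationError, ODEModel, solve
from .pipeline import FitResult

__all__ = [
    "EvaluationReport",
    "DegenerateTestError",
    "parameter_errors",
    "function_space_error",
    "paired_wilcoxon",
    "compare_methods",
    "build_report",
]


class DegenerateTestError(ValueError):
    """All paired differences are zero; the signed-rank test is undefined."""


def parameter_errors(
    theta_hat: dict[str, float],
    theta_true: dict[str, float],
    ratio_pairs: tuple[tuple[str, str], ...] = (),
) -> dict[str, float]:
    """Per-parameter absolute errors |theta_hat - theta_true|.

    For each ``(num, den)`` in ``ratio_pairs`` the two individual entries
    are replaced by the absolute error of the ratio num/den (used for
    weakly identifiable pairs).
    """
    if set(theta_hat) != set(theta_true):
        raise ValueError("theta_hat and theta_true must share parameter names")
    collapsed = {name for pair in ratio_pairs for name in pair}
    errors = {
        name: abs(theta_hat[name] - theta_true[name])
        for name in theta_true
        if name not in collapsed
    }
    for num, den in ratio_pairs:
        if theta_hat[den] == 0 or theta_true[den] == 0:
            raise ValueError(f"ratio denominator {den!r} is zero")
        errors[f"{num}/{den}"] = abs(
            theta_hat[num] / theta_hat[den] - theta_true[num] / theta_true[den]
        )
    return errors


def function_space_error(
    model: ODEModel,
    theta_hat,
    theta_true,
    x0,
    grid,
    rtol: float = 1e-6,
    atol: float = 1e-8,
) -> float:
    """RMS over grid points and states of x(t; theta_hat) - x(t; theta_true).

    A failed solve at theta_hat counts as infinitely bad (divergent
    dynamics are maximal error); a failed solve at the truth raises.
    """
    grid = np.sort(np.asarray(grid, dtype=float).ravel())
    span = (float(grid[0]), float(grid[-1]))
    truth = solve(model, theta_true, x0, span, t_eval=grid, rtol=rtol, atol=atol)
    try:
        est = solve(model, theta_hat, x0, span, t_eval=grid, rtol=rtol, atol=atol)
    except (IntegrationError, ValueError):
        return np.inf
    if est.states.shape != truth.states.shape:
        return np.inf
    return float(np.sqrt(np.mean((est.states - truth.states) ** 2)))


def paired_wilcoxon(errors_a, errors_b) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired differences A - B.

    Zero differences are dropped (classic convention).  The exact null
    distribution is used for n <= 25 without ties, otherwise the normal
    approximation with tie correction.
    """
    a = np.asarray(errors_a, dtype=float).ravel()
    b = np.asarray(errors_b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    if np.all(a == b):
        raise DegenerateTestError("all paired differences are zero")
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


@dataclass
class EvaluationReport:
    """Paired per-replicate errors, summary differences and test results.

    ``records`` is a long-format table: one row per (snr, parameter/metric,
    method, replicate) with its absolute error.  ``comparisons`` holds, per
    (snr, metric), the baseline-minus-candidate improvement distribution
    summary and the Wilcoxon p-value (None when undefined).
    """

    model_name: str
    baseline: str
    candidate: str
    records: pd.DataFrame
    comparisons: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "model_name": self.model_name,
            "baseline": self.baseline,
            "candidate": self.candidate,
            "metadata": self.metadata,
            "comparisons": self.comparisons.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=float))


def _error_rows(
    dataset: Dataset,
    fit: FitResult,
    model: ODEModel,
    method: str,
    replicate: int,
    ratio_pairs,
    fs_grid_points: int,
) -> list[dict]:
    truth = dataset.truth
    if truth is None or truth.get("theta") is None:
        raise ValueError("dataset lacks ground truth; cannot score fits")
    rows = []
    perr = parameter_errors(fit.theta_hat, truth["theta"], ratio_pairs)
    for name, err in perr.items():
        rows.append(
            {
                "snr_db": dataset.snr_db,
                "metric": name,
                "method": method,
                "replicate": replicate,
                "error": err,
            }
        )
    grid = np.linspace(dataset.times[0], dataset.times[-1], fs_grid_points)
    fs = function_space_error(model, fit.theta_hat, truth["theta"], truth["x0"], grid)
    rows.append(
        {
            "snr_db": dataset.snr_db,
            "metric": "function_rms",
            "method": method,
            "replicate": replicate,
            "error": fs,
        }
    )
    return rows


def build_report(
    datasets: list[Dataset],
    fits_by_method: dict[str, list[FitResult]],
    model: ODEModel,
    ratio_pairs: tuple[tuple[str, str], ...] = (),
    fs_grid_points: int = 200,
    alpha: float = 0.05,
) -> EvaluationReport:
    """Score stored fits and run paired tests; deterministic given its inputs."""
    methods = list(fits_by_method)
    if len(methods) < 2:
        raise ValueError("need at least two methods to compare")
    for m, fits in fits_by_method.items():
        if len(fits) != len(datasets):
            raise ValueError(f"method {m!r} has {len(fits)} fits for {len(datasets)} datasets")
    baseline, candidate = methods[0], methods[1]

    rows = []
    for m in methods:
        for rep, (ds, fit) in enumerate(zip(datasets, fits_by_method[m])):
            rows.extend(_error_rows(ds, fit, model, m, rep, ratio_pairs, fs_grid_points))
    records = pd.DataFrame(rows)

    comparisons = []
    for (snr, metric), group in records.groupby(["snr_db", "metric"], sort=True):
        wide = group.pivot_table(index="replicate", columns="method", values="error")
        if baseline not in wide or candidate not in wide:
            continue
        paired = wide[[baseline, candidate]].dropna()
        diffs = (paired[baseline] - paired[candidate]).to_numpy()
        entry = {
            "snr_db": snr,
            "metric": metric,
            "n_pairs": int(paired.shape[0]),
            "median_improvement": float(np.median(diffs)) if diffs.size else np.nan,
            "p_value": None,
            "significant": False,
            "insufficient_data": paired.shape[0] < 3,
        }
        if not entry["insufficient_data"]:
            try:
                _, p = paired_wilcoxon(paired[baseline], paired[candidate])
                entry["p_value"] = p
                entry["significant"] = bool(p < alpha)
            except DegenerateTestError:
                entry["p_value"] = None
        comparisons.append(entry)
    return EvaluationReport(
        model_name=model.name,
        baseline=baseline,
        candidate=candidate,
        records=records,
        comparisons=pd.DataFrame(comparisons),
        metadata={
            "n_datasets": len(datasets),
            "alpha": alpha,
            "ratio_pairs": [list(p) for p in ratio_pairs],
            "fs_grid_points": fs_grid_points,
        },
    )


def compare_methods(
    suite: list[Dataset],
    methods: dict,
    model: ODEModel,
    cfg=None,
    seed: int = 0,
    ratio_pairs: tuple[tuple[str, str], ...] = (),
    fs_grid_points: int = 200,
    alpha: float = 0.05,
) -> EvaluationReport:
    """Fit every method on every dataset of the suite, then build the report.

    ``methods`` maps a name to a callable ``(dataset, model, cfg, seed) ->
    FitResult``; the first entry is treated as the baseline.
    """
    if len(methods) < 2:
        raise ValueError("need at least two methods to compare")
    fits_by_method = {
        name: [fitter(ds, model, cfg, seed=seed + i) for i, ds in enumerate(suite)]
        for name, fitter in methods.items()
    }
    return build_report(
        suite,
        fits_by_method,
        model,
        ratio_pairs=ratio_pairs,
        fs_grid_points=fs_grid_points,
        alpha=alpha,
    )


def plot_comparison(report: EvaluationReport, path: str | Path) -> None:
    """Optional box-plot rendering of the improvement distributions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rec = report.records
    metrics = sorted(rec["metric"].unique())
    fig, axes = plt.subplots(1, len(metrics), figsize=(3 * len(metrics), 4), squeeze=False)
    for ax, metric in zip(axes[0], metrics):
        sub = rec[rec["metric"] == metric]
        data, labels = [], []
        for snr, grp in sub.groupby("snr_db"):
            wide = grp.pivot_table(index="replicate", columns="method", values="error")
            if report.baseline in wide and report.candidate in wide:
                diffs = (wide[report.baseline] - wide[report.candidate]).dropna()
                data.append(diffs.to_numpy())
                labels.append(f"{snr:g}")
        if data:
            ax.boxplot(data, tick_labels=labels)
        ax.axhline(0.0, linestyle="--", color="grey")
        ax.set_title(metric)
        ax.set_xlabel("SNR (dB)")
    axes[0][0].set_ylabel(f"|{report.baseline} err| - |{report.candidate} err|")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
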