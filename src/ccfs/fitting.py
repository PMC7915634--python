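"""Condition aggregation and least-squares fitting of the W-vs-parameter models.

Per-curve detachment works are grouped by acquisition condition (retract
speed, approach speed, delay time, setpoint or delay mode) into
:class:`ConditionSummary` distributions, and the condition *means* are fitted
with the registered two-parameter models by nonlinear least squares
(scipy ``curve_fit``) with deterministic, documented initial guesses.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .curve_io import AnalysisError
from .models import MODEL_REGISTRY, ModelSpec

log = logging.getLogger("ccfs")

__all__ = [
    "ConditionSummary",
    "FitResult",
    "FitError",
    "CONDITION_VARIABLES",
    "aggregate_by_condition",
    "summaries_from_table",
    "fit_model",
    "fit_power_law",
    "bootstrap_condition_ci",
]

CONDITION_VARIABLES = (
    "retract_speed",
    "approach_speed",
    "delay_time",
    "setpoint",
    "delay_mode",
)


class FitError(RuntimeError):
    """Model fit failed (non-convergence or under-determined input)."""


@dataclass
class ConditionSummary:
    """Distribution of detachment work at one acquisition condition."""

    variable: str
    value: object
    values: np.ndarray
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 1:
            raise ValueError("a condition summary needs at least one curve")
        self.degenerate = self.values.size < 2

    @property
    def n_curves(self) -> int:
        return int(self.values.size)

    @property
    def mean_W(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd_W(self) -> float:
        return float(np.std(self.values, ddof=1)) if self.values.size > 1 else 0.0

    @property
    def median_W(self) -> float:
        return float(np.median(self.values))


@dataclass
class FitResult:
    """Fitted parameters of one W-vs-parameter model."""

    model: ModelSpec
    A: float
    B: float
    se_A: float
    se_B: float
    rss: float
    n_points: int

    def predict(self, x):
        return self.model(np.asarray(x, dtype=float), self.A, self.B)


def aggregate_by_condition(results, variable: str) -> list[ConditionSummary]:
    """Group unflagged per-curve results by one acquisition variable.

    Returns one summary per distinct condition value, sorted ascending (delay
    modes sort lexically).  Flagged results are excluded; an empty input
    yields an empty list with a warning.
    """
    if variable not in CONDITION_VARIABLES:
        raise ValueError(f"unknown condition variable {variable!r}; use one of {CONDITION_VARIABLES}")
    groups: dict = {}
    for r in results:
        if getattr(r, "flag", None):
            continue
        key = r.metadata.value_of(variable)
        key = key.value if hasattr(key, "value") else key
        groups.setdefault(key, []).append(r.work)
    if not groups:
        log.warning("aggregate_by_condition: no unflagged results to aggregate")
        return []
    return [
        ConditionSummary(variable=variable, value=k, values=np.asarray(groups[k]))
        for k in sorted(groups)
    ]


def summaries_from_table(frame, column: str, variable: str | None = None) -> list[ConditionSummary]:
    """Build condition summaries from a results table (the curve_io CSV).

    ``frame`` is a pandas DataFrame with a ``work_fJ`` column and the sweep
    column ``column`` (e.g. ``delay_time_s``).
    """
    if column not in frame.columns:
        raise KeyError(f"results table has no column {column!r}")
    if "work_fJ" not in frame.columns:
        raise KeyError("results table has no column 'work_fJ'")
    out = []
    for value, sub in sorted(frame.groupby(column), key=lambda kv: kv[0]):
        out.append(
            ConditionSummary(
                variable=variable or column,
                value=value,
                values=sub["work_fJ"].to_numpy(dtype=float),
            )
        )
    return out


def fit_model(
    summaries,
    model_id: str,
    weighting: str = "none",
    *,
    per_curve: bool = False,
    fixed: dict | None = None,
    max_nfev: int = 10000,
) -> FitResult:
    """Least-squares fit of condition means (or pooled curves) to one model.

    Parameters
    ----------
    summaries : list of ConditionSummary
    model_id : one of ``MODEL_REGISTRY`` ("delay", "setpoint", "approach",
        "retract").
    weighting : "none" fits the plain means; "inverse_variance" weights each
        point by its standard error of the mean.
    per_curve : pool all per-curve values instead of fitting group means.
    fixed : overrides for the model's fixed constants (e.g. ``{"tau": 45.0}``
        for the approach model).

    Initial guesses are deterministic, derived from the first/last data
    points (documented per model in :mod:`ccfs.models`); B is bounded below
    by 0 for the delay and setpoint models.
    """
    if model_id not in MODEL_REGISTRY:
        raise FitError(f"unknown model {model_id!r}; valid ids: {sorted(MODEL_REGISTRY)}")
    spec = MODEL_REGISTRY[model_id]
    if fixed:
        spec = dataclasses.replace(spec, fixed={**spec.fixed, **fixed})
    if weighting not in ("none", "inverse_variance"):
        raise ValueError("weighting must be 'none' or 'inverse_variance'")

    summaries = sorted(summaries, key=lambda s: s.value)
    if per_curve:
        x = np.concatenate([np.full(s.n_curves, float(s.value)) for s in summaries])
        y = np.concatenate([s.values for s in summaries])
        sigma = None
    else:
        x = np.array([float(s.value) for s in summaries])
        y = np.array([s.mean_W for s in summaries])
        sigma = None
        if weighting == "inverse_variance":
            sem = np.array([s.sd_W / np.sqrt(s.n_curves) for s in summaries])
            if np.all(sem > 0):
                sigma = sem
            else:
                log.warning("zero SEM in a group; falling back to unweighted fit")

    n_params = 2
    if np.unique(x).size < n_params + 1:
        raise FitError(
            f"need at least {n_params + 1} condition points for a {n_params}-parameter model, "
            f"got {np.unique(x).size}"
        )

    p0 = np.clip(spec.initial_guess(x, y), spec.bounds[0], spec.bounds[1])
    try:
        popt, pcov = curve_fit(
            spec, x, y, p0=p0, sigma=sigma, absolute_sigma=False,
            bounds=spec.bounds, max_nfev=max_nfev,
        )
    except RuntimeError as exc:
        raise FitError(f"{model_id} fit did not converge: {exc}") from exc
    if not np.all(np.isfinite(popt)):
        raise FitError(f"{model_id} fit produced non-finite parameters")
    resid = y - spec(x, *popt)
    se = np.sqrt(np.abs(np.diag(pcov)))
    return FitResult(
        model=spec,
        A=float(popt[0]),
        B=float(popt[1]),
        se_A=float(se[0]),
        se_B=float(se[1]),
        rss=float(np.sum(resid**2)),
        n_points=int(x.size),
    )


def fit_power_law(x, y) -> tuple[float, float]:
    """Free-exponent power-law fit W = C·x^γ via log-log linear regression.

    Returns ``(C, gamma)``; requires strictly positive x and y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit requires positive x and y")
    res = linregress(np.log(x), np.log(y))
    return float(np.exp(res.intercept)), float(res.slope)


def bootstrap_condition_ci(
    summary: ConditionSummary, n_boot: int = 2000, seed: int = 0, level: float = 0.95
) -> tuple[float, float]:
    """Seeded percentile bootstrap CI of the condition mean work.

    With fewer than 3 curves the CI is degenerate: (min, max) is returned
    with a warning.
    """
    vals = summary.values
    if summary.n_curves < 3:
        log.warning("bootstrap CI degenerate for n=%d curves; returning (min, max)", summary.n_curves)
        return float(np.min(vals)), float(np.max(vals))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, vals.size, size=(n_boot, vals.size))
    means = vals[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)
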