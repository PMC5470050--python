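"""Inverse problems: estimate model parameters from observed rates or
time courses.

The flagship use is the back-calculation of the intracellular NAD+ pool of
loaded cells from a single measured initial ethanol-oxidation rate: the
forward map NAD0 -> initial rate is monotone over physiological pools, so
the estimate is a bracketed root solve, with the observation's reported
uncertainty propagated through the locally linearized inverse map.

``fit_timecourse`` generalizes to bounded least squares on a sampled
trajectory (residuals on ethanol by default, the measured species), with a
deterministic multi-start.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq, least_squares

from .model import ExperimentConfig, TimeCourse, integrate
from .scenarios import DEFAULT_RATE_WINDOW_H, initial_rate

__all__ = [
    "FitProblem",
    "FitResult",
    "NoSolutionError",
    "model_initial_rate",
    "fit_scalar_rate",
    "fit_timecourse",
]

#: parameters that may be freed, with how they act on an ExperimentConfig
_FREE_PARAMS = ("nad0_uM", "adh_scale", "ald_scale", "ldh_scale", "vin")


class NoSolutionError(RuntimeError):
    """The observed rate lies outside what the model can attain on the
    bracket; reports the attainable range."""

    def __init__(self, observed: float, attainable: tuple[float, float]):
        super().__init__(
            f"observed rate {observed:g} is outside the attainable range "
            f"[{attainable[0]:g}, {attainable[1]:g}] on the given bracket"
        )
        self.observed = observed
        self.attainable = attainable


@dataclass(frozen=True)
class FitProblem:
    """A parameter-estimation problem.

    ``free`` maps parameter names (subset of ``nad0_uM``, ``adh_scale``,
    ``ald_scale``, ``ldh_scale``, ``vin``) to positive (lo, hi) bounds.
    ``observed_rate`` (mmol/l_RBCs·h, with optional ``observed_sd``) selects
    the scalar route; ``observed_timecourse`` the trajectory route.
    """

    config: ExperimentConfig
    free: Mapping[str, tuple[float, float]]
    observed_rate: float | None = None
    observed_sd: float | None = None
    observed_timecourse: TimeCourse | None = None
    rate_window_h: tuple[float, float] = (0.0, DEFAULT_RATE_WINDOW_H)
    residual_species: Sequence[str] = ("ethanol_mM",)

    def __post_init__(self) -> None:
        if not self.free:
            raise ValueError("at least one free parameter is required")
        for name, (lo, hi) in self.free.items():
            if name not in _FREE_PARAMS:
                raise ValueError(f"unknown free parameter {name!r}; expected one of {_FREE_PARAMS}")
            if not (0 < lo < hi):
                raise ValueError(f"bounds for {name!r} must satisfy 0 < lo < hi")
        if (self.observed_rate is None) == (self.observed_timecourse is None):
            raise ValueError("provide exactly one of observed_rate / observed_timecourse")


@dataclass(frozen=True)
class FitResult:
    estimates: dict[str, float]
    units: dict[str, str]
    objective: float
    converged: bool
    uncertainty: dict[str, float] = field(default_factory=dict)
    flags: tuple[str, ...] = ()
    residuals: np.ndarray | None = None


def _apply(config: ExperimentConfig, params: Mapping[str, float]) -> ExperimentConfig:
    cfg = config
    enzymes = dict(cfg.enzymes)
    for name, value in params.items():
        if name == "nad0_uM":
            cfg = replace(cfg, nad0_uM=float(value))
        elif name == "vin":
            cfg = replace(cfg, pyruvate_regime=replace(cfg.pyruvate_regime, value=float(value)))
        else:
            enz = name[:3].upper()
            enzymes[enz] = config.enzymes[enz].scaled(float(value))
    if enzymes != dict(config.enzymes):
        cfg = replace(cfg, enzymes=enzymes)
    return cfg


def model_initial_rate(
    config: ExperimentConfig, window_h: tuple[float, float] = (0.0, DEFAULT_RATE_WINDOW_H)
) -> float:
    """Forward map: simulate the config and return its initial rate
    (mmol/l_RBCs·h, or mmol/l·h cell-free)."""
    # integrate only the window itself; keeps the inverse solve cheap
    t1 = window_h[1]
    grid = np.linspace(window_h[0] if window_h[0] > 0 else 0.0, t1, 16)
    short = replace(config, duration_h=t1, sampling_grid_h=grid)
    return initial_rate(integrate(short), window_h).value


def fit_scalar_rate(problem: FitProblem) -> FitResult:
    """Invert the model against one observed initial rate.

    Requires exactly one free parameter.  Verifies the monotonicity of the
    parameter -> rate map on the bracket, then solves by bisection-safe
    root finding; the observation uncertainty (if given) is propagated as
    ``sd_theta = sd_rate / |d rate / d theta|`` at the solution.
    """
    if problem.observed_rate is None:
        raise ValueError("fit_scalar_rate needs a scalar observed_rate")
    if len(problem.free) != 1:
        raise ValueError("fit_scalar_rate requires exactly one free parameter")
    (name, (lo, hi)), = problem.free.items()

    def rate_at(theta: float) -> float:
        return model_initial_rate(_apply(problem.config, {name: theta}), problem.rate_window_h)

    # monotonicity check on a coarse bracket scan
    thetas = np.geomspace(lo, hi, 9)
    rates = np.array([rate_at(t) for t in thetas])
    diffs = np.diff(rates)
    if not (np.all(diffs >= -1e-9 * np.abs(rates[:-1]).max()) or np.all(diffs <= 1e-9 * np.abs(rates[:-1]).max())):
        raise RuntimeError(
            f"model rate is not monotone in {name!r} on [{lo:g}, {hi:g}]; cannot root-solve"
        )
    observed = problem.observed_rate
    r_lo, r_hi = min(rates[0], rates[-1]), max(rates[0], rates[-1])
    if not (r_lo <= observed <= r_hi):
        raise NoSolutionError(observed, (r_lo, r_hi))

    theta_hat = brentq(lambda t: rate_at(t) - observed, lo, hi, xtol=1e-10 * hi, rtol=1e-10)
    uncertainty: dict[str, float] = {}
    if problem.observed_sd is not None:
        h = 1e-4 * theta_hat
        drate = (rate_at(theta_hat + h) - rate_at(theta_hat - h)) / (2 * h)
        if drate != 0:
            uncertainty[name] = abs(problem.observed_sd / drate)
    units = {name: "µM" if name == "nad0_uM" else ("mmol/l_RBCs·h" if name == "vin" else "×")}
    return FitResult(
        estimates={name: float(theta_hat)},
        units=units,
        objective=abs(rate_at(theta_hat) - observed),
        converged=True,
        uncertainty=uncertainty,
    )


def _start_points(bounds: list[tuple[float, float]], n_starts: int, seed: int) -> np.ndarray:
    """Deterministic multi-start points: midpoint + seeded log-uniform draws."""
    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    mid = np.sqrt(lo * hi)
    draws = np.exp(rng.uniform(np.log(lo), np.log(hi), size=(n_starts - 1, len(bounds))))
    return np.vstack([mid, draws])


def fit_timecourse(problem: FitProblem, *, n_starts: int = 5, seed: int = 2024) -> FitResult:
    """Bounded least squares of the model against a sampled time course.

    Residuals are taken on the species in ``problem.residual_species``
    (ethanol only by default).  ``n_starts`` deterministic starts are run
    and the best objective wins; ties break lexicographically on the
    parameter vector.  Structural non-identifiability is flagged when the
    objective surface is flat across starts that end far apart.
    """
    tc = problem.observed_timecourse
    if tc is None:
        raise ValueError("fit_timecourse needs an observed_timecourse")
    if len(tc.time_h) < 4:
        raise ValueError("need at least 4 samples to fit a time course")
    names = list(problem.free)
    bounds = [problem.free[n] for n in names]
    t_obs = tc.time_h
    grid = np.unique(np.concatenate([[0.0], t_obs]))
    obs = np.concatenate([tc.data[s].to_numpy() for s in problem.residual_species])

    def residuals(theta: np.ndarray) -> np.ndarray:
        cfg = _apply(problem.config, dict(zip(names, theta)))
        cfg = replace(cfg, duration_h=max(cfg.duration_h, t_obs[-1]), sampling_grid_h=grid)
        sim = integrate(cfg).data.set_index("time_h").loc[t_obs]
        pred = np.concatenate([sim[s].to_numpy() for s in problem.residual_species])
        return pred - obs

    best = None
    solutions = []
    for x0 in _start_points(bounds, n_starts, seed):
        try:
            res = least_squares(
                residuals, x0, bounds=([b[0] for b in bounds], [b[1] for b in bounds]),
                xtol=1e-10, ftol=1e-12, gtol=1e-12,
            )
        except Exception:
            continue
        solutions.append(res)
        key = (res.cost, tuple(res.x))
        if best is None or key < (best.cost, tuple(best.x)):
            best = res
    if best is None:
        raise RuntimeError("no least-squares start converged")
    flags: list[str] = []
    # flat-objective / scattered-solution identifiability flag
    near = [s for s in solutions if s.cost <= best.cost * (1 + 1e-3) + 1e-12]
    if len(near) > 1:
        spread = np.max([np.abs(s.x - best.x) / np.maximum(best.x, 1e-12) for s in near], axis=0)
        for n, sp in zip(names, spread):
            if sp > 0.05:
                flags.append(f"parameter {n!r} poorly identified (equivalent optima spread {sp:.1%})")
    units = {n: ("µM" if n == "nad0_uM" else ("mmol/l_RBCs·h" if n == "vin" else "×")) for n in names}
    return FitResult(
        estimates={n: float(v) for n, v in zip(names, best.x)},
        units=units,
        objective=float(best.cost),
        converged=bool(best.success),
        flags=tuple(flags),
        residuals=best.fun,
    )
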