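"""Synthetic in-vitro-like assay data.

Emulates the ethanol (and optionally pyruvate) determinations of the
alcocyte incubation experiments: a latent trajectory from the ODE model,
sampled every 30–60 minutes over ~5 h, with multiplicative Gaussian
measurement noise and a detection floor.  For clamped-pyruvate runs the
micropump's manual regulation is mimicked by a seeded, per-interval
piecewise-constant jitter of the clamp target (±20% by default).

Every dataset records its seed, design and latent truth in
``TimeCourse.meta`` so that it can be regenerated bit-identically and used
as ground truth in parameter-recovery studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import ExperimentConfig, TimeCourse, integrate

__all__ = ["NoiseModel", "AssayDesign", "generate_timecourse", "generate_recovery_suite"]

_MEASURABLE = {"ethanol": "ethanol_mM", "pyruvate": "pyruvate_uM"}


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative Gaussian measurement noise with a detection floor.

    ``cv`` is the coefficient of variation (fraction); measured values are
    ``x * (1 + cv * z)`` truncated below at ``floor`` (mM for ethanol), so
    noise never produces negative concentrations.  The default CV of 5% is
    a modeling choice consistent in magnitude with the ± scatter reported
    on measured initial rates.
    """

    kind: str = "multiplicative_gaussian"
    cv: float = 0.05
    floor_mM: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind != "multiplicative_gaussian":
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.cv < 0 or self.floor_mM < 0:
            raise ValueError("cv and floor must be nonnegative")


@dataclass(frozen=True)
class AssayDesign:
    """Sampling plan of one incubation assay.

    Default: samples every 30 min over 5 h (the experimental interval floor),
    ethanol measured; ``clamp_jitter`` is the relative accuracy of the
    maintained pyruvate level under a clamp regime.
    """

    times_h: Sequence[float] = field(default_factory=lambda: tuple(np.arange(0.0, 5.01, 0.5)))
    replicates: int = 1
    measured: Sequence[str] = ("ethanol",)
    clamp_jitter: float = 0.2

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        if t.ndim != 1 or len(t) < 2 or not np.all(np.diff(t) > 0):
            raise ValueError("sampling times must be a strictly increasing 1-D sequence")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        unknown = [m for m in self.measured if m not in _MEASURABLE]
        if unknown:
            raise ValueError(f"cannot measure {unknown}; measurable: {sorted(_MEASURABLE)}")
        if not 0 <= self.clamp_jitter < 1:
            raise ValueError("clamp_jitter must lie in [0, 1)")


def _latent_trajectory(config: ExperimentConfig, design: AssayDesign, rng: np.random.Generator) -> TimeCourse:
    """Integrate the latent truth; a clamped run is integrated piecewise with
    the clamp target perturbed once per sampling interval."""
    times = np.asarray(design.times_h, dtype=float)
    grid = np.unique(np.concatenate([[0.0], times]))
    if config.pyruvate_regime.kind != "clamp" or design.clamp_jitter == 0:
        cfg = replace(config, duration_h=max(config.duration_h, grid[-1]), sampling_grid_h=grid)
        return integrate(cfg)
    # piecewise-constant jittered clamp target
    pieces = []
    state_overrides: dict = {}
    target0 = config.pyruvate_regime.value
    for t0, t1 in zip(grid[:-1], grid[1:]):
        factor = 1.0 + design.clamp_jitter * rng.uniform(-1.0, 1.0)
        cfg = replace(
            config,
            pyruvate_regime=replace(config.pyruvate_regime, value=target0 * factor),
            duration_h=t1 - t0,
            sampling_grid_h=np.array([0.0, t1 - t0]),
            **state_overrides,
        )
        tc = integrate(cfg)
        row = tc.data.iloc[-1]
        state_overrides = dict(
            ethanol0_mM=float(row.ethanol_mM),
            nadh0_uM=float(row.nadh_uM),
            acetaldehyde0_uM=float(row.acetaldehyde_uM),
            lactate0_uM=float(row.lactate_uM),
            acetate0_mM=float(row.acetate_mM),
        )
        seg = tc.data.copy()
        seg["time_h"] += t0
        pieces.append(seg.iloc[[-1]] if t0 > 0 else seg)
    data = pd.concat(pieces, ignore_index=True).reset_index(drop=True)
    data["time_h"] = grid  # exact grid times (offset sums can drift by 1 ulp)
    return TimeCourse(data=data, config=config, meta={"jittered_clamp": True})


def generate_timecourse(
    config: ExperimentConfig, design: AssayDesign, noise: NoiseModel
) -> TimeCourse:
    """Simulate one noisy assay dataset (replicates stacked long-form in a
    ``replicate`` column when ``design.replicates > 1``).

    The returned ``meta`` holds the seed, CV, floor, design and the latent
    (noise-free) values; identical inputs regenerate the dataset exactly.
    """
    rng = np.random.default_rng(noise.seed)
    latent = _latent_trajectory(config, design, rng)
    times = np.asarray(design.times_h, dtype=float)
    lat = latent.data.set_index("time_h").loc[times]
    frames = []
    for rep in range(design.replicates):
        out = pd.DataFrame({"time_h": times})
        for species in design.measured:
            col = _MEASURABLE[species]
            truth = lat[col].to_numpy()
            z = rng.standard_normal(len(times))
            noisy = truth * (1.0 + noise.cv * z)
            floor = noise.floor_mM if col.endswith("_mM") else noise.floor_mM * 1e3
            out[col] = np.maximum(noisy, floor)
        out["replicate"] = rep
        frames.append(out)
    data = pd.concat(frames, ignore_index=True)
    if design.replicates == 1:
        data = data.drop(columns="replicate")
    meta = {
        "synthetic": True,
        "seed": noise.seed,
        "cv": noise.cv,
        "floor_mM": noise.floor_mM,
        "design": {
            "times_h": [float(t) for t in times],
            "replicates": design.replicates,
            "measured": list(design.measured),
            "clamp_jitter": design.clamp_jitter,
        },
        "latent": {c: lat[c].tolist() for c in latent.data.columns if c != "time_h"},
        "latent_residuals": latent.meta.get("residuals"),
    }
    return TimeCourse(data=data, config=config, meta=meta)


def generate_recovery_suite(
    base_config: ExperimentConfig,
    true_params: Mapping[str, Sequence[float]],
    cv_grid: Sequence[float],
    seeds: Sequence[int],
    design: AssayDesign | None = None,
) -> tuple[list[TimeCourse], pd.DataFrame]:
    """A reproducible grid of datasets for estimator benchmarking.

    ``true_params`` maps config field names (e.g. ``nad0_uM``) to value
    grids; the full cross product with ``cv_grid`` × ``seeds`` is generated.
    Returns the datasets and a truth table (one row per dataset) for
    recovery scoring.
    """
    if not seeds:
        raise ValueError("seed list must be nonempty")
    if not cv_grid or any(cv < 0 for cv in cv_grid):
        raise ValueError("cv_grid must be nonempty and nonnegative")
    if design is None:
        design = AssayDesign()
    names = list(true_params)
    grids = [list(true_params[n]) for n in names]
    if any(len(g) == 0 for g in grids):
        raise ValueError("parameter grids must be nonempty")
    datasets: list[TimeCourse] = []
    rows = []
    idx = 0
    combos = [[]]
    for g in grids:
        combos = [c + [v] for c in combos for v in g]
    for combo in combos:
        cfg = replace(base_config, **dict(zip(names, combo)))
        for cv in cv_grid:
            for seed in seeds:
                tc = generate_timecourse(cfg, design, NoiseModel(cv=cv, seed=int(seed)))
                tc.meta["dataset_id"] = idx
                datasets.append(tc)
                rows.append({"dataset_id": idx, **dict(zip(names, combo)), "cv": cv, "seed": int(seed)})
                idx += 1
    return datasets, pd.DataFrame(rows)
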