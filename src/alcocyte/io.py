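"""Tabular and configuration I/O.

Time courses travel as plain CSV with unit-bearing column names
(``time_h``, ``ethanol_mM``, ...); configurations as a versioned YAML
schema with explicit unit strings in every key — the published conditions
mix µM, mM, nkat, µkat and IU, and silent unit bugs are the dominant risk.
Synthetic datasets carry a YAML sidecar (``<name>.meta.yaml``) with seed,
design and latent truth sufficient to regenerate them exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .model import ExperimentConfig, PyruvateRegime, TimeCourse
from .rates import EnzymeLevel

__all__ = [
    "read_timecourse",
    "write_timecourse",
    "load_config",
    "save_config",
    "config_to_dict",
    "config_from_dict",
    "RunManifest",
    "SchemaError",
]

SCHEMA_VERSION = 1


class SchemaError(ValueError):
    """A file violates the expected schema; the message names offending
    columns/lines."""


def write_timecourse(tc: TimeCourse, path: str | Path, *, sidecar: bool = None) -> None:
    """Write a time course as CSV (full float precision, round-trip safe).

    Synthetic datasets (``meta['synthetic']``) also get a ``.meta.yaml``
    sidecar with seed, design and latent truth unless ``sidecar=False``.
    """
    path = Path(path)
    tc.data.to_csv(path, index=False, float_format="%.17g")
    write_sidecar = tc.meta.get("synthetic", False) if sidecar is None else sidecar
    if write_sidecar:
        meta = _jsonable(tc.meta)
        if tc.config is not None:
            meta["config"] = config_to_dict(tc.config)
        with open(path.with_name(path.stem + ".meta.yaml"), "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=False)


def read_timecourse(path: str | Path) -> TimeCourse:
    """Read a time-course CSV, enforcing the schema.

    Requires ``time_h`` and ``ethanol_mM`` columns, numeric cells (localized
    decimal commas are rejected, not silently misparsed) and strictly
    increasing time; violations raise :class:`SchemaError` naming the
    offending column or data lines (1-based, header = line 1).
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    missing = [c for c in ("time_h", "ethanol_mM") if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    has_replicate = "replicate" in raw.columns
    numeric = {}
    for col in raw.columns:
        # exact correctly-rounded parsing (pd.to_numeric is lossy on strings)
        values = np.empty(len(raw), dtype=float)
        bad = []
        for i, v in enumerate(raw[col].to_numpy()):
            if isinstance(v, float):  # missing cell
                values[i] = v
                continue
            try:
                values[i] = float(v)
            except (TypeError, ValueError):
                bad.append(i + 2)  # 1-based, header is line 1
        if bad:
            raise SchemaError(f"{path.name}: non-numeric value(s) in column {col!r} at line(s) {bad[:5]}")
        numeric[col] = values
    data = pd.DataFrame(numeric)
    t = data["time_h"].to_numpy()
    if has_replicate:
        ok = all(np.all(np.diff(g["time_h"].to_numpy()) > 0) for _, g in data.groupby("replicate"))
    else:
        ok = bool(np.all(np.diff(t) > 0))
    if not ok:
        diffs = np.diff(t)
        bad_lines = [int(i) + 3 for i in np.nonzero(diffs <= 0)[0][:5]]
        raise SchemaError(f"{path.name}: time_h not strictly increasing at line(s) {bad_lines}")
    meta: dict = {}
    sidecar = path.with_name(path.stem + ".meta.yaml")
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
    config = None
    if "config" in meta:
        config = config_from_dict(meta["config"])
    return TimeCourse(data=data, config=config, meta=meta)


# --------------------------------------------------------------------------
# configuration schema


def config_to_dict(config: ExperimentConfig) -> dict[str, Any]:
    enzymes = {
        name: {"vmax_f_uM_per_s": lvl.vmax_f, "vmax_r_uM_per_s": lvl.vmax_r}
        for name, lvl in config.enzymes.items()
    }
    regime = {"kind": config.pyruvate_regime.kind}
    if config.pyruvate_regime.kind == "clamp":
        regime["target_uM"] = config.pyruvate_regime.value
    elif config.pyruvate_regime.kind == "bolus":
        regime["initial_uM"] = config.pyruvate_regime.value
    elif config.pyruvate_regime.kind == "influx":
        regime["vin_mmol_per_l_rbc_h"] = config.pyruvate_regime.value
    out = {
        "schema_version": SCHEMA_VERSION,
        "hematocrit": config.hematocrit,
        "nad0_uM": config.nad0_uM,
        "nadh0_uM": config.nadh0_uM,
        "ethanol0_mM": config.ethanol0_mM,
        "acetaldehyde0_uM": config.acetaldehyde0_uM,
        "lactate0_uM": config.lactate0_uM,
        "acetate0_mM": config.acetate0_mM,
        "pyruvate_regime": regime,
        "duration_h": config.duration_h,
        "enzymes": enzymes,
        "integrator": {"rtol": config.rtol, "atol_uM": config.atol},
    }
    if config.sampling_grid_h is not None:
        out["sampling_grid_h"] = [float(t) for t in config.sampling_grid_h]
    return _jsonable(out)


def config_from_dict(d: dict[str, Any]) -> ExperimentConfig:
    version = d.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SchemaError(f"unsupported config schema_version {version!r} (expected {SCHEMA_VERSION})")
    try:
        regime_d = dict(d["pyruvate_regime"])
        kind = regime_d.pop("kind")
        if kind == "none":
            regime = PyruvateRegime.none()
        elif kind == "clamp":
            regime = PyruvateRegime.clamp(target_uM=float(regime_d["target_uM"]))
        elif kind == "bolus":
            regime = PyruvateRegime.bolus(initial_uM=float(regime_d["initial_uM"]))
        elif kind == "influx":
            regime = PyruvateRegime.influx(vin_mmol_per_l_rbc_h=float(regime_d["vin_mmol_per_l_rbc_h"]))
        else:
            raise SchemaError(f"unknown pyruvate regime kind {kind!r}")
        enzymes = {}
        for name, spec in d["enzymes"].items():
            if "vmax_f_uM_per_s" in spec:
                vr = spec.get("vmax_r_uM_per_s")
                enzymes[name] = EnzymeLevel(name, float(spec["vmax_f_uM_per_s"]), None if vr is None else float(vr))
            else:
                enzymes[name] = EnzymeLevel.from_activity(
                    name,
                    float(spec["activity_nkat_per_ml"]),
                    hematocrit=float(d["hematocrit"]),
                    convention=spec.get("convention", "suspension"),
                )
        integ = d.get("integrator", {})
        grid = d.get("sampling_grid_h")
        return ExperimentConfig(
            enzymes=enzymes,
            hematocrit=float(d["hematocrit"]),
            nad0_uM=float(d["nad0_uM"]),
            nadh0_uM=float(d.get("nadh0_uM", 0.0)),
            ethanol0_mM=float(d["ethanol0_mM"]),
            acetaldehyde0_uM=float(d.get("acetaldehyde0_uM", 0.0)),
            lactate0_uM=float(d.get("lactate0_uM", 0.0)),
            acetate0_mM=float(d.get("acetate0_mM", 0.0)),
            pyruvate_regime=regime,
            duration_h=float(d.get("duration_h", 5.0)),
            sampling_grid_h=None if grid is None else np.asarray(grid, dtype=float),
            rtol=float(integ.get("rtol", 1e-8)),
            atol=float(integ.get("atol_uM", 1e-10)),
        )
    except KeyError as exc:
        raise SchemaError(f"config is missing required key {exc}") from None


def save_config(config: ExperimentConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def load_config(path: str | Path) -> ExperimentConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise SchemaError(f"{Path(path).name}: config file must contain a mapping")
    return config_from_dict(d)


def _jsonable(obj: Any) -> Any:
    """Recursively convert numpy scalars/arrays so YAML/JSON dumps cleanly."""
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


class RunManifest:
    """Inventory of a reproduction run: package version, config hashes,
    seeds, integrator settings and every output file written."""

    def __init__(self, *, seed: int | None = None):
        from . import __version__

        self.payload: dict[str, Any] = {
            "package": "alcocyte",
            "version": __version__,
            "seed": seed,
            "stages": [],
            "outputs": [],
        }

    def add_stage(self, name: str, *, config: ExperimentConfig | None = None, **info: Any) -> None:
        entry: dict[str, Any] = {"stage": name, **_jsonable(info)}
        if config is not None:
            blob = json.dumps(config_to_dict(config), sort_keys=True).encode()
            entry["config_sha256"] = hashlib.sha256(blob).hexdigest()
        self.payload["stages"].append(entry)

    def add_output(self, path: str | Path) -> None:
        self.payload["outputs"].append(str(path))

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(_jsonable(self.payload), fh, indent=2, sort_keys=True)
            fh.write("\n")
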