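"""Kinetic constants for the three dehydrogenases of the alcocyte pathway.

The model describes ethanol oxidation by erythrocytes loaded with alcohol
dehydrogenase (ADH, ethanol -> acetaldehyde) and aldehyde dehydrogenase
(ALD, acetaldehyde -> acetate), with the cells' native lactate dehydrogenase
(LDH, pyruvate + NADH -> lactate + NAD+) regenerating the shared NAD+ pool.

All three enzymes follow ordered bi-bi kinetics.  For each enzyme the
substrate/product roles (a, b, p, q; in binding order) are:

================  ======  ============  =========  ======
enzyme            a       b             p          q
================  ======  ============  =========  ======
ADH               NAD+    ethanol       acetald.   NADH
ALD               NAD+    acetald.      acetate    NADH
LDH               NADH    pyruvate      lactate    NAD+
================  ======  ============  =========  ======

The default constant set ships as a human-readable CSV
(``data/kinetic_constants.csv``) with one row per constant; the same format
is accepted for user overrides.  ALD is modeled as irreversible (no product
Michaelis constants, no reverse turnover), with dead-end NADH inhibition
through ``K_iq``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, fields, replace
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "KineticConstants",
    "default_constants",
    "load_constants",
    "write_constants",
    "DATA_FILE",
]

DATA_FILE = "kinetic_constants.csv"

#: concentration-like fields (µM)
_CONC_FIELDS = ("k_a", "k_b", "k_p", "k_q", "k_ia", "k_ib", "k_ip", "k_iq")
#: turnover fields (1/s)
_RATE_FIELDS = ("kcat_f", "kcat_r")

#: which fields each enzyme must / may carry
_REQUIRED: dict[str, tuple[str, ...]] = {
    "ADH": _CONC_FIELDS + _RATE_FIELDS,
    "ALD": ("k_a", "k_b", "k_ia", "k_iq", "kcat_f"),
    "LDH": _CONC_FIELDS + _RATE_FIELDS,
}

#: field name -> CSV "name" column and back
_CSV_NAMES = {
    "k_a": "K_a",
    "k_b": "K_b",
    "k_p": "K_p",
    "k_q": "K_q",
    "k_ia": "K_ia",
    "k_ib": "K_ib",
    "k_ip": "K_ip",
    "k_iq": "K_iq",
    "kcat_f": "kcat_f",
    "kcat_r": "kcat_r",
    "k_eq": "K_eq",
}
_FIELD_NAMES = {v: k for k, v in _CSV_NAMES.items()}

_UNITS = {**{f: "uM" for f in _CONC_FIELDS}, "kcat_f": "1/s", "kcat_r": "1/s", "k_eq": "1e-12 M"}

#: original model-table symbols (K11..K38, V11..V32), kept for provenance
_SYMBOLS: dict[tuple[str, str], str] = {
    ("ADH", "k_a"): "K11", ("ADH", "k_b"): "K12", ("ADH", "k_p"): "K13",
    ("ADH", "k_q"): "K14", ("ADH", "k_ia"): "K15", ("ADH", "k_ib"): "K16",
    ("ADH", "k_ip"): "K17", ("ADH", "k_iq"): "K18", ("ADH", "kcat_f"): "V11",
    ("ADH", "kcat_r"): "V12", ("ADH", "k_eq"): "Keq1",
    ("ALD", "k_a"): "K21", ("ALD", "k_b"): "K22", ("ALD", "k_ia"): "K25",
    ("ALD", "k_iq"): "K28", ("ALD", "kcat_f"): "V21",
    ("LDH", "k_a"): "K31", ("LDH", "k_b"): "K32", ("LDH", "k_p"): "K33",
    ("LDH", "k_q"): "K34", ("LDH", "k_ia"): "K35", ("LDH", "k_ib"): "K36",
    ("LDH", "k_ip"): "K37", ("LDH", "k_iq"): "K38", ("LDH", "kcat_f"): "V31",
    ("LDH", "kcat_r"): "V32", ("LDH", "k_eq"): "Keq3",
}


@dataclass(frozen=True)
class KineticConstants:
    """Ordered bi-bi constants for one enzyme.

    Michaelis (``k_a``..``k_q``) and inhibition (``k_ia``..``k_iq``) constants
    are in µM; turnover numbers ``kcat_f``/``kcat_r`` in 1/s.  ``k_eq`` stores
    the printed equilibrium-constant value on its printed scale (units of
    1e-12 M); it enters only the Haldane diagnostic, never the simulation.
    """

    enzyme_id: str
    k_a: float | None = None
    k_b: float | None = None
    k_p: float | None = None
    k_q: float | None = None
    k_ia: float | None = None
    k_ib: float | None = None
    k_ip: float | None = None
    k_iq: float | None = None
    kcat_f: float | None = None
    kcat_r: float | None = None
    k_eq: float | None = None

    def __post_init__(self) -> None:
        if self.enzyme_id not in _REQUIRED:
            raise ValueError(
                f"unknown enzyme_id {self.enzyme_id!r}; expected one of {sorted(_REQUIRED)}"
            )
        for name in _REQUIRED[self.enzyme_id]:
            value = getattr(self, name)
            if value is None:
                raise ValueError(f"{self.enzyme_id}: required constant {name!r} is missing")
        for f in fields(self):
            if f.name == "enzyme_id":
                continue
            value = getattr(self, f.name)
            if value is not None and not value > 0:
                raise ValueError(f"{self.enzyme_id}: constant {f.name!r} must be > 0, got {value}")
        if self.enzyme_id == "ALD" and self.kcat_r is not None:
            raise ValueError("ALD is irreversible: kcat_r must be absent")

    @property
    def reversible(self) -> bool:
        return self.kcat_r is not None

    def with_overrides(self, **kwargs: float) -> "KineticConstants":
        return replace(self, **kwargs)


def _rows_to_constants(rows: Iterable[Mapping[str, str]]) -> dict[str, KineticConstants]:
    by_enzyme: dict[str, dict[str, float]] = {}
    for i, row in enumerate(rows, start=2):  # header is line 1
        try:
            enzyme = row["enzyme"].strip()
            name = row["name"].strip()
            value = float(row["value"])
        except (KeyError, ValueError) as exc:
            raise ValueError(f"constants table line {i}: malformed row {dict(row)!r}") from exc
        if name not in _FIELD_NAMES:
            raise ValueError(f"constants table line {i}: unknown constant name {name!r}")
        by_enzyme.setdefault(enzyme, {})[_FIELD_NAMES[name]] = value
    return {enz: KineticConstants(enzyme_id=enz, **vals) for enz, vals in by_enzyme.items()}


@lru_cache(maxsize=1)
def _packaged_constants() -> dict[str, KineticConstants]:
    ref = resources.files("alcocyte.data").joinpath(DATA_FILE)
    reader = csv.DictReader(ref.read_text(encoding="utf-8").splitlines())
    return _rows_to_constants(reader)


def load_constants(path: str | Path | None = None) -> dict[str, KineticConstants]:
    """Load a constants table; with ``path=None`` return the packaged defaults."""
    if path is None:
        return dict(_packaged_constants())  # values are frozen; the dict is the caller's
    text = Path(path).read_text(encoding="utf-8")
    reader = csv.DictReader(text.splitlines())
    return _rows_to_constants(reader)


def write_constants(constants: Mapping[str, KineticConstants], path: str | Path) -> None:
    """Write constants in the same one-row-per-constant CSV format (lossless)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["enzyme", "name", "symbol", "value", "unit"])
        for enz in ("ADH", "ALD", "LDH"):
            if enz not in constants:
                continue
            k = constants[enz]
            for f in fields(k):
                if f.name == "enzyme_id" or getattr(k, f.name) is None:
                    continue
                value = getattr(k, f.name)
                text = repr(value) if value != int(value) else str(int(value))
                writer.writerow(
                    [enz, _CSV_NAMES[f.name], _SYMBOLS[(enz, f.name)], text, _UNITS[f.name]]
                )


def default_constants() -> dict[str, KineticConstants]:
    """The packaged default constant sets for ADH, ALD, and LDH."""
    return load_constants(None)
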