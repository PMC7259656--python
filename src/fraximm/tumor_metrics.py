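"""Observable-level computations: ellipse cross-section areas and dosing.

Tumor size is quantified on coronal histology sections as the area of an
ellipse fitted to the largest cross-section, ``pi * a * b`` with semi-axes
``a = A/2`` and ``b = B/2`` for measured major/minor diameters A and B.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "SizeMeasurement",
    "ellipse_area",
    "dose_per_kg",
    "read_size_csv",
]


@dataclass(frozen=True)
class SizeMeasurement:
    """One animal's tumor-size measurement on a given day."""

    animal_id: str
    day: int
    A_diam: float  # major diameter, mm
    B_diam: float  # minor diameter, mm

    def __post_init__(self) -> None:
        if self.A_diam < 0 or self.B_diam < 0:
            raise ValueError("diameters must be >= 0")
        if self.A_diam < self.B_diam:
            raise ValueError("major diameter must be >= minor diameter")

    @property
    def area(self) -> float:
        return ellipse_area(self.A_diam, self.B_diam)


def ellipse_area(A_diam: float, B_diam: float) -> float:
    """Ellipse area from major and minor *diameters* (mm): pi*(A/2)*(B/2)."""
    if A_diam < 0 or B_diam < 0:
        raise ValueError(f"diameters must be >= 0, got A={A_diam}, B={B_diam}")
    return math.pi * (A_diam / 2.0) * (B_diam / 2.0)


def dose_per_kg(
    dose_mg: float,
    body_mass_g: float,
    round_to: float | None = None,
) -> float:
    """Daily dose in mg per kg body weight.

    With ``round_to`` set, the result is rounded half-away-from-zero to
    the nearest multiple of that step (e.g. a 10 mg dose in a 150 g rat is
    66.67 mg/kg, reported as "approximately 65 mg/kg" at a 5 mg/kg step).
    """
    if body_mass_g <= 0:
        raise ValueError(f"body mass must be > 0 g, got {body_mass_g}")
    if dose_mg < 0:
        raise ValueError(f"dose must be >= 0 mg, got {dose_mg}")
    value = dose_mg / (body_mass_g / 1000.0)
    if round_to is not None:
        if round_to <= 0:
            raise ValueError(f"round_to must be > 0, got {round_to}")
        value = math.floor(value / round_to + 0.5) * round_to
    return value


def read_size_csv(path: str | Path) -> pd.DataFrame:
    """Read per-animal tumor size measurements.

    Expected columns: ``animal_id``, ``group``, ``day``, and either the
    diameter pair ``A_mm``/``B_mm`` or a precomputed ``area_mm2``.  The
    returned frame always carries an ``area_mm2`` column.
    """
    df = pd.read_csv(path)
    required = {"animal_id", "group", "day"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "area_mm2" in df.columns:
        pass
    elif {"A_mm", "B_mm"} <= set(df.columns):
        df["area_mm2"] = [ellipse_area(a, b) for a, b in zip(df["A_mm"], df["B_mm"])]
    else:
        raise ValueError(f"{path}: need either area_mm2 or A_mm/B_mm columns")
    if (df["area_mm2"] < 0).any():
        raise ValueError(f"{path}: negative tumor areas present")
    return df
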