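"""Parameter-Quantity-Shifting / Fitting-Performance (PQS-FP) plane.

A diagnostic coordinate system for the complexity-fitting trade-off: each
model variant is a point ``(X, Y)`` where

* ``X = P - O`` is the trainable-parameter shift against a declared
  reference optimum ``O``, and
* ``Y = g - g0`` is the deviation of the generalization gap
  ``g = Acc_train - Acc_val`` from the reference gap ``g0``.

Quadrants classify the variant: OER (X>0, Y>0) overfitting exacerbation,
OAR (X>0, Y<0) overfitting alleviation, UER (X<0, Y>0) underfitting
exacerbation, UAR (X<0, Y<0) underfitting alleviation. Points with X == 0
or Y == 0 are reported ON_AXIS (the reference maps to the origin).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = ["PQSFPPoint", "reference", "map_point", "map_table"]


class PQSFPError(ValueError):
    pass


QUADRANTS = ("OER", "OAR", "UER", "UAR", "ON_AXIS")


@dataclass
class PQSFPPoint:
    label: str
    params: int
    acc_train: float
    acc_val: float
    g: float
    x: float
    y: float
    quadrant: str


def _as_fraction(value: float, unit: str) -> float:
    if unit == "fraction":
        return float(value)
    if unit == "percent":
        return float(value) / 100.0
    raise PQSFPError(f"unknown accuracy unit {unit!r}; use 'fraction' or 'percent'")


def reference(
    points: pd.DataFrame,
    selection: str | None = None,
    unit: str = "fraction",
) -> tuple[int, float]:
    """Pick the reference optimum ``(O, g0)`` from a table of variants.

    ``points`` needs columns ``label, params, acc_train, acc_val`` and, for
    rule-based selection, ``val_loss``. With no explicit ``selection`` label
    the variant with the lowest validation loss is the benchmark.
    """
    if len(points) == 0:
        raise PQSFPError("cannot select a reference from an empty point set")
    if selection is not None:
        match = points[points["label"] == selection]
        if len(match) == 0:
            raise PQSFPError(f"no point labelled {selection!r}")
        row = match.iloc[0]
    else:
        if "val_loss" not in points.columns:
            raise PQSFPError("rule-based selection requires a val_loss column")
        row = points.loc[points["val_loss"].idxmin()]
    g0 = _as_fraction(row["acc_train"], unit) - _as_fraction(row["acc_val"], unit)
    return int(row["params"]), float(g0)


def _quadrant(x: float, y: float) -> str:
    if x == 0 or y == 0:
        return "ON_AXIS"
    if x > 0:
        return "OER" if y > 0 else "OAR"
    return "UER" if y > 0 else "UAR"


def map_point(
    params: int,
    acc_train: float,
    acc_val: float,
    o: int,
    g0: float,
    label: str = "",
    unit: str = "fraction",
) -> PQSFPPoint:
    """Place one model in the plane relative to the reference ``(O, g0)``."""
    train = _as_fraction(acc_train, unit)
    val = _as_fraction(acc_val, unit)
    for name, v in (("acc_train", train), ("acc_val", val)):
        if not (0.0 <= v <= 1.0):
            raise PQSFPError(f"{name} = {v!r} outside [0, 1]")
    g = train - val
    x = float(params - o)
    y = g - g0
    return PQSFPPoint(label, int(params), train, val, g, x, y, _quadrant(x, y))


def map_table(
    points: pd.DataFrame,
    selection: str | None = None,
    unit: str = "fraction",
) -> pd.DataFrame:
    """Map every row of a variant table; returns (label, g, X, Y, quadrant)."""
    o, g0 = reference(points, selection=selection, unit=unit)
    rows = []
    for _, r in points.iterrows():
        p = map_point(
            r["params"], r["acc_train"], r["acc_val"], o, g0, str(r["label"]), unit
        )
        rows.append(
            {
                "label": p.label,
                "params": p.params,
                "g": p.g,
                "X": p.x,
                "Y": p.y,
                "quadrant": p.quadrant,
            }
        )
    return pd.DataFrame(rows)
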