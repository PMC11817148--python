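"""Contour-map extraction: PLS coefficients back onto the grid.

Each retained descriptor column maps to one grid point and field kind.
The point value is coefficient × column standard deviation ("sd-weighted"
coefficient, pIC50 per sd of field energy), making contour levels
scale-free.  Sign semantics follow the probe conventions: for the
electrostatic field (probe charge +1), positive values mark regions
where positive potential — electron-poor groups — raises predicted
activity ("blue"), negative values the electron-rich "red" regions; for
the steric field positive marks bulk-favored "green", negative the
disfavored "yellow".

Regions are extracted at percentile levels of the nonzero values and
exported as OpenDX scalar grids (z-fastest order) plus a CSV summary.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .field_engine import DescriptorMatrix, GridSpec
from .pls import PLSModel

LABELS = ("favorable_high", "favorable_low", "neutral")


@dataclass
class ContourField:
    """Per-grid-point field importance with optional region labels."""

    grid: GridSpec
    field_kind: str
    point_values: np.ndarray  # (n_points,), zero where column filtered out
    upper_level: float | None = None
    lower_level: float | None = None
    region_labels: np.ndarray | None = None  # (n_points,) of LABELS

    def __post_init__(self) -> None:
        if len(self.point_values) != self.grid.n_points:
            raise ValueError("point_values length must equal grid point count")

    def region_summary(self) -> pd.DataFrame:
        """CSV-ready table: point_index, x, y, z, field, value, label."""
        pts = self.grid.points()
        labels = (
            self.region_labels
            if self.region_labels is not None
            else np.full(self.grid.n_points, "neutral", dtype=object)
        )
        return pd.DataFrame({
            "point_index": np.arange(self.grid.n_points),
            "x": pts[:, 0], "y": pts[:, 1], "z": pts[:, 2],
            "field": self.field_kind,
            "value": self.point_values,
            "label": labels,
        })


def coefficient_field(
    model: PLSModel, dm: DescriptorMatrix, field_kind: str
) -> ContourField:
    """sd-weighted coefficients of one field kind mapped to grid points.

    Columns removed by filtering carry value 0.
    """
    if field_kind not in set(dm.field_kind):
        raise ValueError(f"field kind {field_kind!r} absent from descriptor matrix")
    if len(model.coefficients) != dm.n_columns:
        raise ValueError("model was not fitted on this descriptor matrix")
    values = np.zeros(dm.grid.n_points)
    mask = dm.field_kind == field_kind
    values[dm.point_index[mask]] = model.coefficients[mask] * dm.column_sds[mask]
    return ContourField(grid=dm.grid, field_kind=field_kind, point_values=values)


def extract_regions(
    cf: ContourField, upper_pct: float = 90.0, lower_pct: float = 10.0
) -> ContourField:
    """Label points above/below percentile levels of the nonzero values.

    Levels are percentiles of the nonzero point values; points strictly
    above the upper level are ``favorable_high``, strictly below the
    lower level ``favorable_low``, all else ``neutral``.  With constant
    nonzero values both levels coincide and everything stays neutral.
    """
    if not 0 <= lower_pct < upper_pct <= 100:
        raise ValueError("need 0 <= lower_pct < upper_pct <= 100")
    nonzero = cf.point_values[cf.point_values != 0]
    labels = np.full(cf.grid.n_points, "neutral", dtype=object)
    if len(nonzero) == 0:
        warnings.warn("all contour values are zero; no regions extracted", stacklevel=2)
        return ContourField(cf.grid, cf.field_kind, cf.point_values, None, None, labels)
    upper = float(np.percentile(nonzero, upper_pct))
    lower = float(np.percentile(nonzero, lower_pct))
    nz = cf.point_values != 0  # filtered-out points stay neutral
    labels[(cf.point_values > upper) & nz] = "favorable_high"
    labels[(cf.point_values < lower) & nz] = "favorable_low"
    return ContourField(cf.grid, cf.field_kind, cf.point_values, upper, lower, labels)


def write_dx(cf: ContourField, path: str | Path) -> None:
    """Write the point values as an OpenDX scalar grid (z-fastest order)."""
    grid = cf.grid
    nx, ny, nz = grid.counts
    ox, oy, oz = grid.origin
    s = grid.spacing
    lines = [
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {ox:.6f} {oy:.6f} {oz:.6f}",
        f"delta {s:.6f} 0.000000 0.000000",
        f"delta 0.000000 {s:.6f} 0.000000",
        f"delta 0.000000 0.000000 {s:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {grid.n_points} data follows",
    ]
    vals = cf.point_values
    for i in range(0, len(vals), 3):
        lines.append(" ".join(f"{v:.8e}" for v in vals[i : i + 3]))
    lines += [
        'attribute "dep" string "positions"',
        'object "regular positions regular connections" class field',
        'component "positions" value 1',
        'component "connections" value 2',
        'component "data" value 3',
        "",
    ]
    Path(path).write_text("\n".join(lines))


def read_dx(path: str | Path, field_kind: str = "unknown") -> ContourField:
    """Read back an OpenDX scalar grid written by :func:`write_dx`."""
    text = Path(path).read_text()
    m = re.search(r"gridpositions counts (\d+) (\d+) (\d+)", text)
    counts = tuple(int(c) for c in m.groups())
    origin = tuple(float(v) for v in re.search(
        r"origin ([\-\d.eE+]+) ([\-\d.eE+]+) ([\-\d.eE+]+)", text).groups())
    deltas = re.findall(r"delta ([\-\d.eE+]+) ([\-\d.eE+]+) ([\-\d.eE+]+)", text)
    spacing = float(deltas[0][0])
    data_match = re.search(r"data follows\n(.*?)\nattribute", text, re.S)
    values = np.array([float(v) for v in data_match.group(1).split()])
    grid = GridSpec(origin=origin, spacing=spacing, counts=counts)
    return ContourField(grid=grid, field_kind=field_kind, point_values=values)
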