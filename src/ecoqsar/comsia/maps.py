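"""StDev*Coeff contour maps of a fitted field model.

For one field the map value at each lattice point is the regression
coefficient times the descriptor standard deviation at that point — the
quantity conventionally contoured to show where adding bulk/charge/
hydrophobicity is predicted to raise or lower the response.  Favored and
disfavored masks are percentile cuts of the positive and negative values.
Maps export as OpenDX grids plus a flat CSV point list.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fields import FieldGrid
from .pls import PLSModel

__all__ = ["ContourMap", "contour_map", "write_opendx", "write_point_csv"]


@dataclass
class ContourMap:
    field: str
    grid: FieldGrid
    values: np.ndarray  # StDev*Coeff per lattice point (0 where filtered)
    favored_mask: np.ndarray
    disfavored_mask: np.ndarray
    favored_level: float
    disfavored_level: float


def contour_map(
    model: PLSModel,
    grid: FieldGrid,
    field: str,
    favored_percentile: float = 80.0,
    disfavored_percentile: float = 20.0,
) -> ContourMap:
    """Build the StDev*Coeff lattice and its favored/disfavored masks.

    Favored points are those above the ``favored_percentile`` of the positive
    map values; disfavored points are below the ``disfavored_percentile`` of
    the negative values.  Filtered-out columns contribute exactly zero.
    """
    if model.field_labels is None:
        raise ValueError("model carries no field labels")
    labels = np.asarray(model.field_labels)
    in_field = labels == field
    if not in_field.any():
        raise ValueError(f"model has no columns for field {field!r}")
    if int(in_field.sum()) != grid.n_points:
        raise ValueError("grid does not match the model's column layout")
    full = np.zeros(labels.size)
    full[model.mask] = model.coef * model.x_std
    values = full[in_field]

    pos = values[values > 0]
    neg = values[values < 0]
    favored_level = float(np.percentile(pos, favored_percentile)) if pos.size else np.inf
    disfavored_level = float(np.percentile(neg, disfavored_percentile)) if neg.size else -np.inf
    favored = values > favored_level if pos.size else np.zeros_like(values, dtype=bool)
    disfavored = values < disfavored_level if neg.size else np.zeros_like(values, dtype=bool)
    return ContourMap(field=field, grid=grid, values=values,
                      favored_mask=favored, disfavored_mask=disfavored,
                      favored_level=favored_level, disfavored_level=disfavored_level)


def write_opendx(cmap: ContourMap, path) -> None:
    """Write the map as an OpenDX regular-grid scalar file."""
    g = cmap.grid
    nx, ny, nz = g.shape
    with open(path, "w") as fh:
        fh.write(f"# ecoqsar StDev*Coeff map, field {cmap.field}\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {g.origin[0]:.6f} {g.origin[1]:.6f} {g.origin[2]:.6f}\n")
        fh.write(f"delta {g.spacing:.6f} 0 0\n")
        fh.write(f"delta 0 {g.spacing:.6f} 0\n")
        fh.write(f"delta 0 0 {g.spacing:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {cmap.values.size} data follows\n"
        )
        vals = cmap.values
        for start in range(0, vals.size, 3):
            fh.write(" ".join(f"{v:.6e}" for v in vals[start : start + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "regular positions regular connections" class field\n')
        fh.write('component "positions" value 1\n')
        fh.write('component "connections" value 2\n')
        fh.write('component "data" value 3\n')


def write_point_csv(cmap: ContourMap, path) -> None:
    """Write a per-point CSV: coordinates, value, favored/disfavored flags."""
    pts = cmap.grid.points()
    df = pd.DataFrame(
        {
            "x": pts[:, 0],
            "y": pts[:, 1],
            "z": pts[:, 2],
            "stdev_coeff": cmap.values,
            "favored": cmap.favored_mask.astype(int),
            "disfavored": cmap.disfavored_mask.astype(int),
        }
    )
    df.to_csv(path, index=False)
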