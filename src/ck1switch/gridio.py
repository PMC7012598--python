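"""Regular 3-D grid maps and OpenDX text I/O.

A :class:`GridMap` holds per-point open-fraction values on a regular,
axis-aligned grid, optionally restricted by a boolean mask (points inside
the union of inclusion spheres). OpenDX files carry the dense value array
(z fastest), with zeros outside the mask, which is what molecular viewers
expect for contouring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["GridMap", "write_grid_map", "read_grid_map"]


@dataclass
class GridMap:
    origin: np.ndarray  # Å, position of grid point (0, 0, 0)
    spacing: float  # Å, isotropic
    dims: tuple[int, int, int]
    values: np.ndarray  # open fraction in [0, 1], shape == dims
    mask: np.ndarray | None = None  # True inside the sphere union

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != tuple(self.dims):
            raise ValueError(
                f"values shape {self.values.shape} does not match dims {self.dims}"
            )
        if self.mask is not None and self.mask.shape != tuple(self.dims):
            raise ValueError("mask shape does not match dims")

    @property
    def n_points(self) -> int:
        return int(np.prod(self.dims))

    def points(self) -> np.ndarray:
        """Dense (n, 3) array of grid point coordinates, C order (z fastest)."""
        axes = [
            self.origin[k] + self.spacing * np.arange(self.dims[k]) for k in range(3)
        ]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def masked_values(self) -> np.ndarray:
        """Values at masked (in-region) points; all values if no mask."""
        if self.mask is None:
            return self.values.ravel()
        return self.values[self.mask]


def write_grid_map(grid: GridMap, path: str | Path) -> None:
    """Write a grid map as an OpenDX scalar field (text, 6 sig. figures).

    Values must lie in [0, 1]; points outside the mask are written as 0.
    """
    vals = grid.masked_values()
    if vals.size and (vals.min() < 0 or vals.max() > 1):
        raise ValueError(
            f"grid values outside [0, 1]: min={vals.min()}, max={vals.max()}"
        )
    dense = np.where(grid.mask, grid.values, 0.0) if grid.mask is not None else grid.values
    flat = dense.ravel(order="C")
    nx, ny, nz = grid.dims
    s = grid.spacing
    lines = [
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        "origin {:.6g} {:.6g} {:.6g}".format(*grid.origin),
        f"delta {s:.6g} 0 0",
        f"delta 0 {s:.6g} 0",
        f"delta 0 0 {s:.6g}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {flat.size} data follows",
    ]
    for i in range(0, flat.size, 3):
        lines.append(" ".join(f"{v:.6g}" for v in flat[i : i + 3]))
    lines += [
        'attribute "dep" string "positions"',
        'object "open fraction" class field',
        'component "positions" value 1',
        'component "connections" value 2',
        'component "data" value 3',
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_grid_map(path: str | Path) -> GridMap:
    """Read an OpenDX scalar field written by :func:`write_grid_map`."""
    dims: tuple[int, int, int] | None = None
    origin = None
    deltas: list[float] = []
    data: list[float] = []
    n_items = None
    reading = False
    for line in Path(path).read_text().splitlines():
        tok = line.split()
        if not tok:
            continue
        if reading:
            if tok[0] == "attribute" or tok[0] == "object":
                reading = False
            else:
                data.extend(float(t) for t in tok)
                continue
        if tok[:4] == ["object", "1", "class", "gridpositions"]:
            dims = (int(tok[-3]), int(tok[-2]), int(tok[-1]))
        elif tok[0] == "origin":
            origin = np.array([float(t) for t in tok[1:4]])
        elif tok[0] == "delta":
            deltas.append(max(float(t) for t in tok[1:4]))
        elif tok[0] == "object" and "data" in tok and "follows" in tok:
            n_items = int(tok[tok.index("items") + 1])
            reading = True
    if dims is None or origin is None or n_items is None:
        raise ValueError(f"{path}: not a recognizable OpenDX grid file")
    if len(data) != n_items:
        raise ValueError(f"{path}: expected {n_items} values, found {len(data)}")
    if len(set(np.round(deltas, 9))) != 1:
        raise ValueError(f"{path}: anisotropic grids are not supported")
    values = np.array(data).reshape(dims, order="C")
    return GridMap(origin=origin, spacing=deltas[0], dims=dims, values=values)
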