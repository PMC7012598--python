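"""Grid-based free volume of the substrate-binding cleft and anion sites.

The region of interest is the union of (by default three) overlapping
spheres covering the substrate binding cleft and the adjacent anion
binding sites. A regular grid is laid over the union; for each trajectory
frame a grid point is "closed" if it falls within the van der Waals radius
of any protein heavy atom, and the free volume is the count of open points
times the voxel volume. Averaging the per-frame open/closed indicator over
frames yields an open-fraction map whose 0.10 contour marks regions that
were consistently open — the same quantity POVME-style tools compute.

Waters, ions and sulfates must be stripped beforehand and frames
superposed to a common reference; hydrogens are ignored (crystal frames
lack them).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .gridio import GridMap
from .structures import Ensemble, Structure

__all__ = [
    "SphereRegion",
    "PocketSpec",
    "VolumeSeries",
    "BONDI_RADII",
    "build_grid",
    "frame_free_volume",
    "ensemble_frequency_map",
    "contour_map",
    "default_pocket_spec",
]

logger = logging.getLogger(__name__)

#: Bondi van der Waals radii (Å) for elements common in proteins.
BONDI_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "SE": 1.90,
}


@dataclass(frozen=True)
class SphereRegion:
    center: tuple[float, float, float]  # Å
    radius: float  # Å

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"sphere radius must be positive, got {self.radius}")


@dataclass
class PocketSpec:
    """Inclusion spheres, grid spacing and occlusion radii.

    ``frame_stride`` subsamples trajectory frames (papers state a time
    stride like "every two ns"; files store frames — use
    :meth:`stride_for_interval` to convert when frame times are known).
    """

    spheres: list[SphereRegion]
    grid_spacing: float = 1.0  # Å
    radii_table: dict[str, float] = field(default_factory=lambda: dict(BONDI_RADII))
    frame_stride: int = 1
    probe_padding: float = 0.0  # optional padding added to every radius

    def __post_init__(self) -> None:
        if not self.spheres:
            raise ValueError("at least one inclusion sphere is required")
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be positive")
        if self.frame_stride < 1:
            raise ValueError("frame_stride must be ≥ 1")

    def stride_for_interval(self, ensemble: Ensemble, interval_ns: float) -> int:
        """Frame stride corresponding to a time interval, given frame times."""
        if ensemble.frame_times is None or len(ensemble.frame_times) < 2:
            raise ValueError("ensemble has no frame times")
        dt = ensemble.frame_times[1] - ensemble.frame_times[0]
        return max(1, int(round(interval_ns / dt)))


@dataclass
class VolumeSeries:
    """Per-frame free volumes (ų) at the configured stride."""

    volumes: np.ndarray
    frame_indices: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.volumes))

    @property
    def sd(self) -> float:
        return float(np.std(self.volumes, ddof=1)) if len(self.volumes) > 1 else 0.0


def build_grid(spec: PocketSpec) -> GridMap:
    """Grid skeleton over the sphere union (mask = inside ≥ 1 sphere).

    The lattice covers the union bounding box; ordering is deterministic
    (C order, z fastest). Raises if no grid point falls inside the union.
    """
    centers = np.array([s.center for s in spec.spheres], dtype=float)
    radii = np.array([s.radius for s in spec.spheres], dtype=float)
    lo = (centers - radii[:, None]).min(axis=0)
    hi = (centers + radii[:, None]).max(axis=0)
    s = spec.grid_spacing
    dims = tuple(int(np.floor((hi[k] - lo[k]) / s)) + 1 for k in range(3))
    grid = GridMap(
        origin=lo,
        spacing=s,
        dims=dims,
        values=np.zeros(dims),
        mask=np.zeros(dims, dtype=bool),
    )
    pts = grid.points()
    inside = np.zeros(len(pts), dtype=bool)
    for c, r in zip(centers, radii):
        inside |= np.sum((pts - c) ** 2, axis=1) <= r * r
    grid.mask = inside.reshape(dims)
    if not grid.mask.any():
        raise ValueError("no grid points fall inside the sphere union")
    return grid


def _occlusion_open_mask(
    frame_coords: np.ndarray,
    topology: Structure,
    spec: PocketSpec,
    region_points: np.ndarray,
    tree: cKDTree,
) -> np.ndarray:
    """Boolean open mask over region points for one frame."""
    open_mask = np.ones(len(region_points), dtype=bool)
    heavy = [
        (i, a.element.upper())
        for i, a in enumerate(topology.atoms)
        if not a.is_hydrogen
    ]
    by_element: dict[str, list[int]] = {}
    for i, el in heavy:
        by_element.setdefault(el, []).append(i)
    for el, idx in by_element.items():
        if el not in spec.radii_table:
            raise KeyError(
                f"element {el!r} missing from the occlusion radii table"
            )
        r = spec.radii_table[el] + spec.probe_padding
        hits = tree.query_ball_point(frame_coords[idx], r)
        for h in hits:
            open_mask[h] = False
    return open_mask


def frame_free_volume(
    frame_coords: np.ndarray,
    topology: Structure,
    spec: PocketSpec,
    grid: GridMap,
) -> tuple[float, np.ndarray]:
    """Free volume (ų) of one frame and its open mask over region points.

    A point is closed iff it lies within ``radii_table[element]`` (+
    optional probe padding) of any protein heavy atom; free volume is the
    open-point count × spacing³.
    """
    region_points = grid.points()[grid.mask.ravel()]
    tree = cKDTree(region_points)
    open_mask = _occlusion_open_mask(
        np.asarray(frame_coords, dtype=float), topology, spec, region_points, tree
    )
    volume = float(open_mask.sum()) * spec.grid_spacing**3
    return volume, open_mask


def ensemble_frequency_map(
    ensemble: Ensemble,
    spec: PocketSpec,
    grid: GridMap | None = None,
    drift_threshold: float = 5.0,
) -> tuple[GridMap, VolumeSeries]:
    """Open-fraction map and per-frame volume series over an ensemble.

    Each grid value is the fraction of analyzed frames in which the point
    was open. Frames are taken every ``spec.frame_stride`` frames. The
    ensemble is expected to be superposed to a common reference already; a
    centroid drift above ``drift_threshold`` Å only triggers a warning,
    because legitimate conformational changes can also move the centroid.
    """
    if grid is None:
        grid = build_grid(spec)
    if len(ensemble.topology.atoms):
        centroids = np.array([f.mean(axis=0) for f in ensemble.frames])
        drift = np.linalg.norm(centroids - centroids[0], axis=1).max()
    else:
        drift = 0.0
    if drift > drift_threshold:
        warnings.warn(
            f"ensemble centroid drifts {drift:.1f} Å; frames may not be "
            "superposed to a common reference",
            stacklevel=2,
        )

    region_points = grid.points()[grid.mask.ravel()]
    tree = cKDTree(region_points)
    indices = np.arange(0, ensemble.n_frames, spec.frame_stride)
    open_counts = np.zeros(len(region_points))
    volumes = np.empty(len(indices))
    for j, i in enumerate(indices):
        open_mask = _occlusion_open_mask(
            ensemble.frames[i], ensemble.topology, spec, region_points, tree
        )
        open_counts += open_mask
        volumes[j] = open_mask.sum() * spec.grid_spacing**3

    values = np.zeros(grid.dims)
    values[grid.mask] = open_counts / len(indices)
    freq = GridMap(
        origin=grid.origin, spacing=grid.spacing, dims=grid.dims,
        values=values, mask=grid.mask.copy(),
    )
    return freq, VolumeSeries(volumes=volumes, frame_indices=indices)


def contour_map(grid: GridMap, level: float = 0.1) -> GridMap:
    """Restrict a frequency map to points with value ≥ ``level``.

    Raising the level never adds points (monotone). The returned map keeps
    the retained values; everything else is masked out and zeroed.
    """
    if not 0 < level <= 1:
        raise ValueError(f"contour level must be in (0, 1], got {level}")
    base_mask = grid.mask if grid.mask is not None else np.ones(grid.dims, dtype=bool)
    keep = base_mask & (grid.values >= level)
    values = np.where(keep, grid.values, 0.0)
    return GridMap(origin=grid.origin, spacing=grid.spacing, dims=grid.dims,
                   values=values, mask=keep)


# residue sets defining the default sphere placement (author numbering)
SITE1_RESIDUES = (178, 224)  # R178, K224
SITE2_RESIDUES = (127, 154, 171)  # R127, K154, K171


def default_pocket_spec(
    structure: Structure,
    chain: str | None = None,
    radius: float = 8.0,
    grid_spacing: float = 1.0,
) -> PocketSpec:
    """Three-sphere pocket spec anchored on the anion-site residues.

    Sphere 1 sits at the heavy-atom centroid of the Site 1 residues (R178,
    K224), sphere 2 at the Site 2 residues (R127, K154, K171), and sphere 3
    — the substrate cleft — at their midpoint; all radii default to 8 Å.
    """
    if chain is None:
        chain = structure.chains()[0]

    def centroid(res_seqs: tuple[int, ...]) -> np.ndarray:
        coords = [
            a.xyz for a in structure.atoms
            if a.chain == chain and a.res_seq in res_seqs and not a.is_hydrogen
        ]
        if not coords:
            raise ValueError(
                f"no heavy atoms found for residues {res_seqs} in chain {chain}"
            )
        return np.mean(np.asarray(coords), axis=0)

    c1 = centroid(SITE1_RESIDUES)
    c2 = centroid(SITE2_RESIDUES)
    c3 = (c1 + c2) / 2.0
    return PocketSpec(
        spheres=[
            SphereRegion(tuple(c1), radius),
            SphereRegion(tuple(c2), radius),
            SphereRegion(tuple(c3), radius),
        ],
        grid_spacing=grid_spacing,
    )
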