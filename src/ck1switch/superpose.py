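"""Kabsch least-squares superposition and segment RMSD traces.

The RMSD traces mirror the standard MD analysis of loop stability: each
trajectory frame is rigidly superposed onto a reference (Kabsch, optionally
weighted), then the RMSD of a residue segment — e.g. the activation loop
(residues 168–175) against the crystallographic "up"/"down" conformations,
or loop L-EF (residues 213–224) against the initial structure — is computed.
By default the fit and the measurement use the same segment, so the trace
equals the optimal superposition RMSD; a core-fit mode (fit on a stable
core, measure the segment without refitting) is available because tools
differ on this convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import (
    AtomSelection,
    Ensemble,
    Structure,
    StructureError,
    select_atoms,
)

__all__ = [
    "SuperpositionResult",
    "RMSDTrace",
    "AveragedTrace",
    "kabsch_superpose",
    "apply_superposition",
    "segment_rmsd_trace",
    "replica_average",
    "pairwise_segment_rmsd",
]


class DegenerateGeometryError(ValueError):
    """Raised when the point set cannot define a unique rotation."""


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid motion mapping mobile onto reference."""

    rotation: np.ndarray  # 3×3 proper rotation
    translation: np.ndarray  # Å
    rmsd: float  # Å


@dataclass
class RMSDTrace:
    """Per-frame segment RMSD (Å) against a named reference."""

    reference_name: str
    segment: AtomSelection
    series: np.ndarray
    frame_times: np.ndarray | None = None
    replica_id: int | str | None = None


@dataclass
class AveragedTrace:
    """Pointwise mean over replica traces; replicas retained."""

    mean: np.ndarray
    replicas: list[RMSDTrace]
    frame_times: np.ndarray | None = None

    @property
    def n_replicas(self) -> int:
        return len(self.replicas)


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Solves for the proper rotation R and translation t minimising the
    (weighted) RMSD of ``mobile @ R.T + t`` to ``reference`` via SVD of the
    cross-covariance matrix, with the determinant sign correction that
    excludes reflections.

    Raises
    ------
    StructureError
        if the point counts differ or fewer than 3 points are given.
    DegenerateGeometryError
        if the points are collinear or coincident, leaving the rotation
        under-determined.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise StructureError(
            f"point count mismatch: mobile {mobile.shape} vs reference {reference.shape}"
        )
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise StructureError("superposition requires ≥ 3 points of shape (n, 3)")

    if weights is None:
        w = np.ones(len(mobile))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(mobile),) or np.any(w < 0) or w.sum() == 0:
            raise StructureError("weights must be non-negative, one per atom")
    wn = w / w.sum()

    mob_center = wn @ mobile
    ref_center = wn @ reference
    x = mobile - mob_center
    y = reference - ref_center

    # collinearity check: the two largest principal extents must be nonzero
    sv_x = np.linalg.svd(x * np.sqrt(wn)[:, None], compute_uv=False)
    scale = max(sv_x[0], 1.0)
    if sv_x[1] < 1e-9 * scale:
        raise DegenerateGeometryError(
            "mobile points are collinear or coincident; rotation is not unique"
        )

    h = (x * wn[:, None]).T @ y
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T

    transformed = x @ rotation.T
    rmsd = float(np.sqrt(np.sum(wn * np.sum((transformed - y) ** 2, axis=1))))
    translation = ref_center - rotation @ mob_center
    return SuperpositionResult(rotation=rotation, translation=translation, rmsd=rmsd)


def apply_superposition(coords: np.ndarray, result: SuperpositionResult) -> np.ndarray:
    """Apply a fitted rigid motion to any coordinate set."""
    return np.asarray(coords, dtype=float) @ result.rotation.T + result.translation


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def segment_rmsd_trace(
    ensemble: Ensemble,
    reference: Structure,
    fit_selection: AtomSelection,
    rmsd_selection: AtomSelection,
    reference_name: str = "custom",
    replica_id: int | str | None = None,
) -> RMSDTrace:
    """Per-frame RMSD of a segment after rigid superposition.

    For every frame, superpose the frame's ``fit_selection`` atoms onto the
    reference's, apply that motion to the whole frame, and measure the
    unweighted RMSD over ``rmsd_selection``. With ``fit_selection ==
    rmsd_selection`` this is the optimal (minimum) segment RMSD; with a
    core fit it reports how far the segment has moved relative to a stable
    frame of reference.
    """
    fit_idx_t = select_atoms(ensemble.topology, fit_selection)
    fit_idx_r = select_atoms(reference, fit_selection)
    out_idx_t = select_atoms(ensemble.topology, rmsd_selection)
    out_idx_r = select_atoms(reference, rmsd_selection)
    if len(fit_idx_t) < 3 or len(fit_idx_r) < 3:
        raise StructureError("fit selection resolves to fewer than 3 atoms")
    if len(fit_idx_t) != len(fit_idx_r):
        raise StructureError(
            f"fit selection size differs: {len(fit_idx_t)} in ensemble vs "
            f"{len(fit_idx_r)} in reference"
        )
    if not out_idx_t or len(out_idx_t) != len(out_idx_r):
        raise StructureError("rmsd selection is empty or mismatched")

    ref_coords = reference.coords
    ref_fit = ref_coords[fit_idx_r]
    ref_out = ref_coords[out_idx_r]

    series = np.empty(ensemble.n_frames)
    for i, frame in enumerate(ensemble.frames):
        sup = kabsch_superpose(frame[fit_idx_t], ref_fit)
        moved = apply_superposition(frame[out_idx_t], sup)
        series[i] = _rmsd(moved, ref_out)

    times = (
        np.asarray(ensemble.frame_times, dtype=float)
        if ensemble.frame_times is not None
        else None
    )
    return RMSDTrace(
        reference_name=reference_name,
        segment=rmsd_selection,
        series=series,
        frame_times=times,
        replica_id=replica_id,
    )


def replica_average(traces: list[RMSDTrace]) -> AveragedTrace:
    """Pointwise arithmetic mean over replica traces (times must match)."""
    if not traces:
        raise StructureError("no traces to average")
    n = len(traces[0].series)
    for t in traces[1:]:
        if len(t.series) != n:
            raise StructureError(
                f"trace length mismatch: {len(t.series)} vs {n}"
            )
        if (t.frame_times is None) != (traces[0].frame_times is None) or (
            t.frame_times is not None
            and not np.allclose(t.frame_times, traces[0].frame_times)
        ):
            raise StructureError("frame times differ between replicas")
    mean = np.mean([t.series for t in traces], axis=0)
    return AveragedTrace(mean=mean, replicas=list(traces),
                         frame_times=traces[0].frame_times)


def pairwise_segment_rmsd(
    structures: list[Structure],
    selection: AtomSelection,
) -> np.ndarray:
    """Matrix of optimal segment RMSDs between all pairs of structures.

    Used, e.g., to check that a loop segment (such as L-EF residues
    210–230, backbone) starts from similar conformations across a set of
    simulation starting structures.
    """
    coord_sets = []
    for s in structures:
        idx = select_atoms(s, selection)
        if len(idx) < 3:
            raise StructureError(f"{s.id}: selection resolves to {len(idx)} atoms")
        coord_sets.append(s.coords[idx])
    n_atoms = {c.shape[0] for c in coord_sets}
    if len(n_atoms) != 1:
        raise StructureError(f"selection sizes differ across structures: {n_atoms}")
    n = len(coord_sets)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = kabsch_superpose(coord_sets[i], coord_sets[j]).rmsd
    return out
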