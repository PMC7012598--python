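"""Essential-dynamics PCA of backbone fluctuations.

Trajectories are reduced to heavy backbone atoms (N, CA, C, O), superposed
onto one reference (Kabsch), and concatenated; the covariance matrix of
Cartesian fluctuations about the concatenated mean is diagonalized via an
SVD of the centered data matrix. Fitting on the concatenation of several
systems' trajectories and then projecting each system separately puts all
systems in one shared eigenvector space, so their projection histograms
are directly comparable.

Eigenvalues are the variances (Ų) captured by each mode, using the
population normalization (divide by the number of frames): two frames at
amplitudes ±a along one direction therefore give exactly one nonzero
eigenvalue a².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import (
    AtomSelection,
    BACKBONE_ATOMS,
    Ensemble,
    Structure,
    StructureError,
    select_atoms,
)
from .superpose import apply_superposition, kabsch_superpose

__all__ = [
    "PCModel",
    "ProjectionSeries",
    "fit_pc_model",
    "project",
    "histogram_projections",
    "mode_endpoints",
]


@dataclass
class PCModel:
    """Eigenbasis of backbone fluctuations."""

    mean_coords: np.ndarray  # (N, 3), Å — mean over all superposed frames
    eigenvectors: np.ndarray  # (k, 3N), orthonormal rows, descending variance
    eigenvalues: np.ndarray  # (k,), Ų
    atom_indices: list[int]  # into the (reduced) topology
    topology: Structure  # reduced topology the model lives on
    reference_coords: np.ndarray  # (N, 3) — superposition target

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)


@dataclass
class ProjectionSeries:
    """Per-frame projection (Å) of one system on one component."""

    system: str
    component: int
    values: np.ndarray
    bin_edges: np.ndarray | None = None
    counts: np.ndarray | None = None


def _reduce_backbone(ensemble: Ensemble) -> tuple[Ensemble, list[int]]:
    sel = AtomSelection(atom_names=BACKBONE_ATOMS)
    idx = select_atoms(ensemble.topology, sel)
    atoms = [ensemble.topology.atoms[i] for i in idx]
    topo = Structure(id=ensemble.topology.id, atoms=atoms,
                     source_format=ensemble.topology.source_format)
    frames = [f[idx] for f in ensemble.frames]
    return Ensemble(topology=topo, frames=frames,
                    frame_times=ensemble.frame_times), idx


def _superposed_flat(frames: list[np.ndarray], reference: np.ndarray) -> np.ndarray:
    out = np.empty((len(frames), reference.size))
    for i, f in enumerate(frames):
        sup = kabsch_superpose(f, reference)
        out[i] = apply_superposition(f, sup).ravel()
    return out


def fit_pc_model(
    ensembles: list[Ensemble],
    reference: Structure,
    backbone_only: bool = True,
    n_modes: int | None = None,
    superpose: bool = True,
) -> PCModel:
    """Fit a shared eigenbasis on the concatenation of all ensembles.

    All ensembles must share a topology after backbone reduction, and the
    reference must carry the same atoms. ``n_modes`` caps the number of
    stored modes (default: all modes with nonzero variance, at most
    frames − 1). ``superpose=False`` skips the per-frame Kabsch fit for
    data already expressed in a common frame.
    """
    if not ensembles:
        raise StructureError("no ensembles given")

    reduced = []
    keys = None
    for ens in ensembles:
        red = _reduce_backbone(ens)[0] if backbone_only else ens
        key = [(a.chain, a.res_seq, a.name) for a in red.topology.atoms]
        if keys is None:
            keys = key
        elif key != keys:
            raise StructureError("ensembles do not share a topology after reduction")
        reduced.append(red)

    total_frames = sum(e.n_frames for e in reduced)
    if total_frames < 2:
        raise StructureError("PCA requires at least 2 frames in total")

    if backbone_only:
        ref_sel = AtomSelection(atom_names=BACKBONE_ATOMS)
        ref_idx = select_atoms(reference, ref_sel)
    else:
        ref_idx = list(range(len(reference.atoms)))
    ref_coords = reference.coords[ref_idx]
    if ref_coords.shape[0] != len(keys):
        raise StructureError(
            f"reference has {ref_coords.shape[0]} atoms after reduction, "
            f"ensembles have {len(keys)}"
        )

    if superpose:
        x = np.vstack([_superposed_flat(e.frames, ref_coords) for e in reduced])
    else:
        x = np.vstack([[f.ravel() for f in e.frames] for e in reduced])
    mean_flat = x.mean(axis=0)
    xc = x - mean_flat

    # SVD of the centered data matrix: eigenvalues of C = XcᵀXc / F are s²/F
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    eigenvalues = s**2 / x.shape[0]
    k = int(np.sum(s > 1e-10 * max(s[0], 1.0))) or 1
    if n_modes is not None:
        k = min(k, n_modes)
    return PCModel(
        mean_coords=mean_flat.reshape(-1, 3),
        eigenvectors=vt[:k],
        eigenvalues=eigenvalues[:k],
        atom_indices=list(range(len(keys))),
        topology=reduced[0].topology,
        reference_coords=ref_coords,
    )


def project(ensemble: Ensemble, model: PCModel, component: int,
            backbone_only: bool = True, system: str | None = None,
            superpose: bool = True) -> ProjectionSeries:
    """Project an ensemble's frames on one principal component (Å).

    Frames are superposed to the model's reference with the same protocol
    used in fitting, then projected as dot(frame − mean, eigenvector).
    Pass ``superpose=False`` for coordinates already expressed in the
    model frame (e.g. mode endpoints), where an extra fit would be wrong.
    """
    if not 0 <= component < model.n_modes:
        raise IndexError(
            f"component {component} out of range (model has {model.n_modes} modes)"
        )
    red = _reduce_backbone(ensemble)[0] if backbone_only else ensemble
    if len(red.topology.atoms) != len(model.atom_indices):
        raise StructureError(
            "ensemble topology does not map onto the model's atoms"
        )
    if superpose:
        x = _superposed_flat(red.frames, model.reference_coords)
    else:
        x = np.array([f.ravel() for f in red.frames])
    values = (x - model.mean_coords.ravel()) @ model.eigenvectors[component]
    return ProjectionSeries(
        system=system or ensemble.topology.id,
        component=component,
        values=values,
    )


def histogram_projections(series: ProjectionSeries, bin_width: float) -> ProjectionSeries:
    """Histogram a projection series on a symmetric axis (counts sum to n)."""
    if bin_width <= 0:
        raise ValueError(f"bin width must be positive, got {bin_width}")
    if len(series.values) == 0:
        raise ValueError("empty projection series")
    extent = float(np.max(np.abs(series.values)))
    # symmetric range about 0, with 0 at a bin center
    half_bins = max(1, int(np.ceil(extent / bin_width + 0.5)))
    edges = (np.arange(-half_bins, half_bins + 2) - 0.5) * bin_width
    counts, edges = np.histogram(series.values, bins=edges)
    series.bin_edges = edges
    series.counts = counts
    return series


def mode_endpoints(model: PCModel, component: int, amplitude: float) -> tuple[Structure, Structure]:
    """Structures at mean ± amplitude·eigenvector along one mode.

    The midpoint of the two endpoint coordinate sets is exactly the mean
    structure; re-projecting an endpoint on its own component returns
    ±amplitude, and 0 on any orthogonal component.
    """
    if not 0 <= component < model.n_modes:
        raise IndexError(f"component {component} out of range")
    vec = model.eigenvectors[component].reshape(-1, 3)
    plus = model.topology.with_coords(
        model.mean_coords + amplitude * vec, id=f"PC{component + 1}+{amplitude:g}"
    )
    minus = model.topology.with_coords(
        model.mean_coords - amplitude * vec, id=f"PC{component + 1}-{amplitude:g}"
    )
    return plus, minus
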