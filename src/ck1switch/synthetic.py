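"""Synthetic inputs with known ground truth for every pipeline stage.

Every generator is a pure function of its parameters and seed, returns
its ground truth alongside the data, and (where noted) can write standard
formats (PDB, CSV, FASTA) so the pipeline is exercised through its real
I/O paths. Noise models: isotropic Gaussian on coordinates, multiplicative
Gaussian on assay signals; the regression-panel generator adds Gaussian
noise to half-life directly, matching the ordinary-least-squares
generative model it is meant to probe.

The toy kinase emulates the activation-loop switch geometry: a
backbone-only chain (residues 140–240) carrying the three probe atoms,
with L173 CD2 placed 4 Å from L152 CD2 and 12 Å from the Y225 hydroxyl in
the "up" state, and the reverse in "down" — a built-in separation of 8 Å
between the two distance profiles. The three probe atoms are laid out
collinearly, which keeps the distance *difference* maximally stable under
isotropic coordinate noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .pocket import PocketSpec, SphereRegion
from .structures import Atom, Ensemble, Structure

__all__ = [
    "TOY_SEPARATION",
    "make_toy_kinase",
    "make_switch_ensemble",
    "make_mode_trajectory",
    "make_pocket_scene",
    "make_alignment",
    "simulate_progress_curves",
    "simulate_decay",
    "simulate_phosphoswitch_panel",
]

#: Built-in separation (Å) between the two distance profiles of the toy
#: kinase: |d_L152 − d_Y225| = 8 in both states.
TOY_SEPARATION = 8.0

_UP_DISTANCES = (4.0, 12.0)  # (d_L152, d_Y225) in the "up" state
# L152:CD2 at x = 0 and Y225:OH at x = 8; L173:CD2 sits OUTSIDE the anchor
# segment (x = −4 "up", x = +12 "down"), so both distance gradients point
# the same way and coordinate noise perturbs the two distances coherently
_ANCHOR_SEPARATION = 8.0


def _backbone_residue(res_seq: int, res_name: str, chain: str,
                      origin: np.ndarray, serial0: int) -> list[Atom]:
    # minimal rigid residue: N, CA, C, O around an origin point
    offsets = {
        "N": (-0.7, -0.6, 0.0),
        "CA": (0.0, 0.0, 0.0),
        "C": (0.8, 0.6, 0.0),
        "O": (0.9, 1.4, 0.7),
    }
    atoms = []
    for i, (name, off) in enumerate(offsets.items()):
        atoms.append(
            Atom(
                serial=serial0 + i,
                name=name,
                element=name[0],
                res_name=res_name,
                res_seq=res_seq,
                chain=chain,
                altloc="",
                occupancy=1.0,
                xyz=tuple(origin + np.asarray(off)),
            )
        )
    return atoms


def make_toy_kinase(seed: int = 0, state: str = "up", chain: str = "A") -> Structure:
    """Small kinase-like structure with the three switch probe atoms.

    Backbone (N, CA, C, O) for residues 140–240 laid along a gentle helix;
    residues 152 and 173 are LEU with a CD2 atom, residue 225 is TYR with
    an OH. In state "up": d(L173 CD2, L152 CD2) = 4 Å and
    d(L173 CD2, Y225 OH) = 12 Å; "down" swaps the two distances. The
    output is deterministic for a given (seed, state).
    """
    if state not in ("up", "down"):
        raise ValueError(f"state must be 'up' or 'down', got {state!r}")
    rng = np.random.default_rng(seed)
    # the seed only rotates the helix phase; geometry is otherwise fixed
    phase = rng.uniform(0, 2 * np.pi)

    atoms: list[Atom] = []
    serial = 1
    special = {152: "LEU", 173: "LEU", 225: "TYR"}
    for res_seq in range(140, 241):
        i = res_seq - 140
        origin = np.array(
            [
                20.0 + 6.0 * np.cos(0.35 * i + phase),
                20.0 + 6.0 * np.sin(0.35 * i + phase),
                10.0 + 1.5 * i * 0.25,
            ]
        )
        res_name = special.get(res_seq, "ALA")
        res_atoms = _backbone_residue(res_seq, res_name, chain, origin, serial)
        serial += len(res_atoms)
        atoms.extend(res_atoms)

    # probe atoms on a fixed collinear axis, independent of the helix
    x_mobile = -_UP_DISTANCES[0] if state == "up" else _ANCHOR_SEPARATION + _UP_DISTANCES[0]
    probes = [
        ("CD2", "C", "LEU", 152, np.array([0.0, 0.0, 0.0])),
        ("CD2", "C", "LEU", 173, np.array([x_mobile, 0.0, 0.0])),
        ("OH", "O", "TYR", 225, np.array([_ANCHOR_SEPARATION, 0.0, 0.0])),
    ]
    for name, element, res_name, res_seq, xyz in probes:
        atoms.append(
            Atom(
                serial=serial, name=name, element=element, res_name=res_name,
                res_seq=res_seq, chain=chain, altloc="", occupancy=1.0,
                xyz=tuple(xyz),
            )
        )
        serial += 1
    atoms.sort(key=lambda a: (a.chain, a.res_seq, a.name != "N", a.name))
    return Structure(id=f"toy-kinase-{state}", atoms=atoms)


def make_switch_ensemble(
    n_up: int,
    n_down: int,
    noise_sigma: float,
    seed: int,
) -> tuple[Ensemble, list[str]]:
    """Ensemble of toy-kinase frames in known states with coordinate noise.

    Frames are the "up" toy structure (first ``n_up`` frames) and the
    "down" structure (next ``n_down``), each perturbed by isotropic
    Gaussian noise of s.d. ``noise_sigma`` Å on every coordinate. Returns
    the ensemble and the per-frame ground-truth labels.
    """
    if n_up + n_down < 1:
        raise ValueError("need at least one frame (n_up + n_down ≥ 1)")
    if n_up < 0 or n_down < 0 or noise_sigma < 0:
        raise ValueError("counts and noise must be non-negative")
    rng = np.random.default_rng(seed)
    up = make_toy_kinase(seed=seed, state="up")
    down = make_toy_kinase(seed=seed, state="down")

    labels = ["up"] * n_up + ["down"] * n_down
    frames = []
    for label in labels:
        base = up.coords if label == "up" else down.coords
        frames.append(base + rng.normal(0.0, noise_sigma, size=base.shape))
    return Ensemble(topology=up, frames=frames), labels


def make_mode_trajectory(
    base: Structure,
    modes: Sequence[tuple[np.ndarray, float]],
    n_frames: int,
    noise_sigma: float,
    seed: int,
) -> tuple[Ensemble, dict]:
    """Trajectory dominated by prescribed collective modes.

    frames = base + Σᵢ aᵢ(t)·modeᵢ + noise, with aᵢ(t) ~ N(0, varianceᵢ).
    Mode vectors are orthonormalized (Gram–Schmidt); if that changes a
    vector beyond numerical tolerance the change is recorded in the
    returned ground truth (``"orthogonalized": True``).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be ≥ 1")
    n3 = base.coords.size
    vecs, variances = [], []
    changed = False
    for vec, var in modes:
        if var <= 0:
            raise ValueError("mode variances must be positive")
        v = np.asarray(vec, dtype=float).ravel()
        if v.size != n3:
            raise ValueError(f"mode vector length {v.size} != 3N = {n3}")
        orig = v / np.linalg.norm(v)
        for u in vecs:
            v = v - (v @ u) * u
        norm = np.linalg.norm(v)
        if norm < 1e-12:
            raise ValueError("modes are linearly dependent")
        v = v / norm
        if not np.allclose(v, orig, atol=1e-9):
            changed = True
        vecs.append(v)
        variances.append(float(var))

    rng = np.random.default_rng(seed)
    amplitudes = np.column_stack(
        [rng.normal(0.0, np.sqrt(var), size=n_frames) for var in variances]
    )
    flat_base = base.coords.ravel()
    frames = []
    for k in range(n_frames):
        flat = flat_base + amplitudes[k] @ np.array(vecs)
        if noise_sigma > 0:
            flat = flat + rng.normal(0.0, noise_sigma, size=n3)
        frames.append(flat.reshape(-1, 3))
    truth = {
        "modes": np.array(vecs),
        "variances": np.array(variances),
        "amplitudes": amplitudes,
        "orthogonalized": changed,
        "noise_sigma": noise_sigma,
    }
    return Ensemble(topology=base, frames=frames), truth


def make_pocket_scene(
    spec: PocketSpec | None = None,
    occlusion: str = "none",
) -> tuple[Structure, PocketSpec, float]:
    """Pocket scene with an analytically known free volume.

    The default spec is a single sphere of radius 8 Å at the origin
    (spacing from the provided spec is honoured). Occlusions:

    - ``"none"``: no atoms; expected free volume = (4/3)πr³ per sphere
      (spheres must be single or pairwise disjoint for the analytic value).
    - ``"center_atom"``: one carbon at the first sphere's center; expected
      deficit = (4/3)π·1.7³ ≈ 20.6 ų.
    - ``"half_slab"``: a dense carbon slab occluding the z < 0 half of the
      first sphere; expected free volume = half the sphere volume.
    """
    if spec is None:
        spec = PocketSpec(spheres=[SphereRegion((0.0, 0.0, 0.0), 8.0)])
    sphere_vol = sum((4.0 / 3.0) * np.pi * s.radius**3 for s in spec.spheres)

    def carbon(serial: int, xyz: np.ndarray) -> Atom:
        return Atom(serial=serial, name="C", element="C", res_name="SLB",
                    res_seq=1, chain="X", altloc="", occupancy=1.0,
                    xyz=tuple(xyz))

    atoms: list[Atom] = []
    if occlusion == "none":
        expected = sphere_vol
    elif occlusion == "center_atom":
        r_c = spec.radii_table.get("C", 1.7)
        atoms.append(carbon(1, np.asarray(spec.spheres[0].center)))
        expected = sphere_vol - (4.0 / 3.0) * np.pi * r_c**3
    elif occlusion == "half_slab":
        if len(spec.spheres) != 1:
            raise ValueError("half_slab scene is defined for a single sphere")
        sph = spec.spheres[0]
        r = sph.radius
        r_c = spec.radii_table.get("C", 1.7)
        s = spec.grid_spacing
        c = np.asarray(sph.center)
        # Lattice of carbons whose vdW spheres close the lower half of the
        # sphere. The top atom plane sits at −r_c − s/2, so the closure
        # boundary (one carbon radius above it) falls exactly on a voxel
        # boundary at z = −s/2: grid points with z ≤ −s are closed, z ≥ 0
        # open, and no point ties on the radius. The expected free volume
        # is the exact spherical-cap volume above that plane.
        step = 0.5
        extent = r + r_c + step
        xs = np.arange(-extent, extent + step, step)
        z_top = -r_c - s / 2.0
        z_planes = np.arange(z_top, -(r + r_c) - 1.0, -1.4)
        serial = 1
        for x in xs:
            for y in xs:
                for z in z_planes:
                    atoms.append(carbon(serial, c + np.array([x, y, z])))
                    serial += 1
        b = -s / 2.0  # closure plane
        expected = np.pi * ((r**2 * r - r**3 / 3.0) - (r**2 * b - b**3 / 3.0))
    else:
        raise ValueError(f"unknown occlusion {occlusion!r}")
    scene = Structure(id=f"pocket-scene-{occlusion}", atoms=atoms)
    return scene, spec, float(expected)


def make_alignment(
    n_sequences: int,
    length: int,
    substitution_p: float,
    seed: int,
    reference_id: str = "REF",
) -> tuple[str, dict]:
    """FASTA alignment text with per-position substitutions off a reference.

    Sequence 1 is the ungapped reference; every other sequence mutates
    each position independently with probability ``substitution_p``.
    Returns the FASTA text and ground truth (reference sequence and the
    substitution matrix).
    """
    rng = np.random.default_rng(seed)
    aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    ref = rng.choice(aa, size=length)
    records = [(reference_id, "".join(ref))]
    substituted = np.zeros((n_sequences - 1, length), dtype=bool)
    for s in range(n_sequences - 1):
        seq = ref.copy()
        flips = rng.random(length) < substitution_p
        for j in np.where(flips)[0]:
            choices = aa[aa != ref[j]]
            seq[j] = rng.choice(choices)
        substituted[s] = flips
        records.append((f"seq{s + 1}", "".join(seq)))
    fasta = "\n".join(f">{name}\n{seq}" for name, seq in records) + "\n"
    return fasta, {"reference": "".join(ref), "substituted": substituted}


def simulate_progress_curves(
    kcat_over_km: float,
    e_total: float = 0.2e-6,  # M — matches the 0.2 µM kinase assay design
    s0: float = 10.0,  # µM substrate
    timepoints: np.ndarray | None = None,  # s; default hourly over 3 hr
    noise_frac: float = 0.02,
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[list, dict]:
    """Pseudo-first-order product curves with multiplicative noise.

    P(t) = S0·(1 − exp(−(kcat/Km)·E·t)) × (1 + ε), ε ~ N(0, noise_frac²).
    Defaults mirror a triplicate endpoint assay: 10 µM substrate, 0.2 µM
    kinase, 3 hr. Returns ProgressCurve replicates and the ground truth.
    """
    from .kinetics import ProgressCurve

    if timepoints is None:
        timepoints = np.arange(0.0, 3.0 * 3600.0 + 1, 1800.0)
    timepoints = np.asarray(timepoints, dtype=float)
    rng = np.random.default_rng(seed)
    clean = s0 * (1.0 - np.exp(-kcat_over_km * e_total * timepoints))
    curves = []
    for rep in range(n_replicates):
        noisy = clean * (1.0 + rng.normal(0.0, noise_frac, size=clean.shape))
        curves.append(
            ProgressCurve(timepoints=timepoints, signal=np.clip(noisy, 0.0, None),
                          replicate=rep, substrate="FASP")
        )
    truth = {
        "kcat_over_km": kcat_over_km, "e_total": e_total, "s0": s0,
        "noise_frac": noise_frac, "clean_signal": clean,
    }
    return curves, truth


def simulate_decay(
    t_half: float,
    y0: float = 100.0,
    plateau: float = 10.0,
    t_chx: float = 0.0,
    duration: float = 24.0,  # hr
    dt: float = 0.25,  # hr — LumiCycle-like sampling
    noise_frac: float = 0.02,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """One-phase luminescence decay with multiplicative noise.

    Y(t) = (y0 − plateau)·exp(−(ln2/t_half)·(t − t_chx)) + plateau for
    t ≥ t_chx. Returns (timepoints, signal, ground truth).
    """
    if t_half <= 0:
        raise ValueError("t_half must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(t_chx, t_chx + duration + dt / 2, dt)
    k = np.log(2.0) / t_half
    clean = (y0 - plateau) * np.exp(-k * (t - t_chx)) + plateau
    noisy = clean * (1.0 + rng.normal(0.0, noise_frac, size=clean.shape))
    truth = {"t_half": t_half, "rate": k, "y0": y0, "plateau": plateau,
             "t_chx": t_chx, "noise_frac": noise_frac}
    return t, noisy, truth


def simulate_phosphoswitch_panel(
    slope: float,
    intercept: float = 2.0,
    n_mutants: int = 8,
    ratio_range: tuple[float, float] = (0.2, 3.0),
    noise_sd: float = 0.3,  # hr, additive on half-life
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Mutant panel with a linear efficiency-ratio → half-life relation.

    Ratios are evenly spaced over ``ratio_range``; half-life = slope·ratio
    + intercept + N(0, noise_sd²). Additive noise keeps the panel inside
    the OLS generative model, so confidence-interval coverage can be
    checked exactly. Returns a tidy table and the ground truth.
    """
    if n_mutants < 2:
        raise ValueError("panel needs at least 2 mutants")
    rng = np.random.default_rng(seed)
    ratios = np.linspace(ratio_range[0], ratio_range[1], n_mutants)
    half_life = slope * ratios + intercept + rng.normal(0.0, noise_sd, size=n_mutants)
    df = pd.DataFrame(
        {
            "mutant": [f"mut{i}" for i in range(n_mutants)],
            "efficiency_ratio": ratios,
            "half_life_hr": half_life,
        }
    )
    truth = {"slope": slope, "intercept": intercept, "noise_sd": noise_sd}
    return df, truth
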