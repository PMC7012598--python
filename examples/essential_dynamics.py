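"""Essential-dynamics PCA of a trajectory with two planted modes.

Generates a backbone trajectory dominated by two orthogonal collective
modes of variance 9 and 4 Ų plus 0.1 Å noise, fits the PCA model
(superpose, concatenate, diagonalize the Cartesian covariance), projects
the frames on PC1/PC2, and builds mode-endpoint structures.
"""

import numpy as np

from ck1switch import fit_pc_model, histogram_projections, mode_endpoints, project
from ck1switch.structures import AtomSelection, BACKBONE_ATOMS, select_atoms
from ck1switch import synthetic as syn

base = syn.make_toy_kinase(0, "up")
idx = select_atoms(base, AtomSelection(atom_names=BACKBONE_ATOMS))
comps = np.repeat(np.array(idx) * 3, 3) + np.tile([0, 1, 2], len(idx))
rng = np.random.default_rng(17)


def backbone_mode():
    v = np.zeros(base.coords.size)
    v[comps] = rng.normal(size=len(comps))
    return v / np.linalg.norm(v)


ensemble, truth = syn.make_mode_trajectory(
    base, [(backbone_mode(), 9.0), (backbone_mode(), 4.0)],
    n_frames=2000, noise_sigma=0.1, seed=23,
)
model = fit_pc_model([ensemble], base)
print(f"leading eigenvalues (Ų): {np.round(model.eigenvalues[:4], 3)}")
print("planted variances: [9, 4]")

pc1 = histogram_projections(project(ensemble, model, 0), bin_width=2.0)
print(f"PC1 projection range: {pc1.values.min():.1f} .. {pc1.values.max():.1f} Å")
print(f"histogram bins: {len(pc1.counts)}, counts sum: {pc1.counts.sum()}")

plus, minus = mode_endpoints(model, 0, amplitude=8.0)
print(f"endpoint ids: {plus.id}, {minus.id}")
print(
    "\nThe two leading eigenvalues recover the planted mode variances; "
    "projections are in Å along each orthonormal mode, and the endpoint "
    "structures visualize the motion at ±8 Å along PC1."
)
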