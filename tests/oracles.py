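"""Independent oracles used by the tests.

These deliberately avoid the code paths they check: the superposition
oracle is Horn's quaternion method (no SVD), and the union-volume oracle
is plain Monte-Carlo sampling.
"""

from __future__ import annotations

import numpy as np


def quaternion_superpose_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Optimal superposition RMSD by Horn's closed-form quaternion method."""
    x = mobile - mobile.mean(axis=0)
    y = reference - reference.mean(axis=0)
    s = x.T @ y
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(k)[-1]
    n = len(x)
    sq = (np.sum(x**2) + np.sum(y**2) - 2.0 * lam) / n
    return float(np.sqrt(max(sq, 0.0)))


def mc_union_volume(centers: np.ndarray, radii: np.ndarray, n_samples: int,
                    rng: np.random.Generator) -> float:
    """Monte-Carlo estimate of the volume of a union of spheres."""
    centers = np.asarray(centers, dtype=float)
    radii = np.asarray(radii, dtype=float)
    lo = (centers - radii[:, None]).min(axis=0)
    hi = (centers + radii[:, None]).max(axis=0)
    box = np.prod(hi - lo)
    pts = rng.uniform(lo, hi, size=(n_samples, 3))
    inside = np.zeros(n_samples, dtype=bool)
    for c, r in zip(centers, radii):
        inside |= np.sum((pts - c) ** 2, axis=1) <= r * r
    return float(box * inside.mean())
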