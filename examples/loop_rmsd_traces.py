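"""Segment RMSD traces of the activation loop against two references.

Emulates the loop-stability analysis of an MD ensemble: frames are
generated around the "up" conformation of a toy kinase, then the RMSD of
the activation-loop segment (residues 168–175, heavy backbone) is traced
against both the "up" and the "down" reference structures after Kabsch
superposition. A trajectory that stays near its starting conformation
keeps RMSD_up low while RMSD_down stays near the up↔down reference
separation.
"""

import numpy as np

from ck1switch import replica_average, segment_rmsd_trace
from ck1switch.structures import AtomSelection
from ck1switch import synthetic as syn

up_ref = syn.make_toy_kinase(0, "up")
down_ref = syn.make_toy_kinase(0, "down")
# all heavy atoms of the loop segment: the up/down references differ in the
# position of the L173 side chain, which the backbone alone cannot see
segment = AtomSelection(res_range=(168, 175))

traces_up, traces_down = [], []
for replica in range(5):
    rng = np.random.default_rng(100 + replica)
    mode = rng.normal(size=up_ref.coords.size)
    ensemble, _ = syn.make_mode_trajectory(
        up_ref, [(mode, 0.5)], n_frames=20, noise_sigma=0.1, seed=replica
    )
    traces_up.append(
        segment_rmsd_trace(ensemble, up_ref, segment, segment, "up", replica)
    )
    traces_down.append(
        segment_rmsd_trace(ensemble, down_ref, segment, segment, "down", replica)
    )

avg_up = replica_average(traces_up)
avg_down = replica_average(traces_down)
print(f"replicas: {avg_up.n_replicas}, frames per replica: {len(avg_up.mean)}")
print(f"mean RMSD_up   (Å): {np.round(avg_up.mean[:8], 3)} ...")
print(f"mean RMSD_down (Å): {np.round(avg_down.mean[:8], 3)} ...")
print(
    "\nRMSD_up stays small (the trajectory fluctuates around the 'up' "
    "reference) while RMSD_down stays near the fixed up–down separation — "
    "the signature of a loop that has not switched conformation."
)
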