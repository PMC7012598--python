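# ck1switch

Analysis tools for the conformational switch in the activation loop of
Casein Kinase 1δ (CK1δ) and its consequences for circadian substrate
selection.

CK1δ/ε phosphorylates the clock protein PERIOD2 (PER2) at two competing
groups of sites: the stabilizing FASP cassette and the degrading Degron —
the "phosphoswitch" that sets circadian period. The kinase's activation
loop sits in two discrete conformations, "loop down" (the common state,
coupled to anion binding at Site 2) and "loop up" (rare, favoured by the
short-period *tau* mutation R178C), and the balance between them biases
the kinase between those substrates. This package implements the
computational layer of that analysis:

- **Loop-switch classification** (`ck1switch.loop_switch`): the position
  of L173 reports the loop state through two interatomic distances —
  d(L173 CD2, L152 CD2), short when the loop is up, and
  d(L173 CD2, Y225 OH), short when the loop is down. Chains and frames
  are classified by direct comparison with a ±1 Å indeterminate margin
  and surveyed across structure libraries.
- **Superposition & segment RMSD** (`ck1switch.superpose`): Kabsch
  least-squares superposition (SVD with reflection correction) and
  per-frame RMSD traces of loop segments — the activation loop (residues
  168–175) against "up"/"down" crystallographic references, loop L-EF
  (213–224) against the initial structure — with replica averaging.
- **Pocket volumetrics** (`ck1switch.pocket`): POVME-style free volume of
  the substrate cleft and anion sites inside three overlapping inclusion
  spheres; per-frame volumes = open grid points × voxel volume, ensemble
  open-fraction maps contoured at 0.10, written as OpenDX.
- **Essential dynamics** (`ck1switch.pca`): backbone-only PCA of
  concatenated, superposed ensembles; eigenvalues in Ų, per-system
  projections in Å, histograms, and mode-endpoint structures.
- **Kinetics** (`ck1switch.kinetics`): apparent second-order efficiency
  kcat/Km from pseudo-first-order endpoints,
  kcat/Km = −ln(1 − P/S₀) / ([E]·t); NMR site ratios with propagated
  uncertainty; one-phase decay Y(t) = (Y₀ − plateau)·e^(−kt) + plateau
  with half-life ln2/k for PER2::LUC stability; and OLS of half-life on
  the FASP/Degron efficiency ratio with a 95% CI band.
- **Conservation** (`ck1switch.conservation`): reference-anchored percent
  identity over a residue patch of a FASTA alignment (gaps = mismatch).
- **Synthetic data** (`ck1switch.synthetic`): generators for every input
  class with known ground truth — two-state switch ensembles, mode-driven
  trajectories, pocket scenes with closed-form free volumes, progress
  curves, decays and mutant panels.

Structure I/O (PDB/mmCIF, multi-model ensembles, author numbering) goes
through [gemmi]; regressions through statsmodels; decay fits through
lmfit.

## Worked example

```python
from ck1switch import survey_ensemble
from ck1switch import synthetic as syn

ensemble, truth = syn.make_switch_ensemble(n_up=3, n_down=2,
                                           noise_sigma=0.3, seed=7)
survey = survey_ensemble(ensemble, margin=1.0)
print(survey.counts)
```

prints

```
{'up': 3, 'down': 2, 'indeterminate': 0}
```

— every frame's label recovered from the two probe distances alone. The
scripts under `examples/` walk through each capability the same way
(`python examples/phosphoswitch_kinetics.py` prints a triplicate
kcat/Km of 508 ± 34 M⁻¹s⁻¹ against a generating value of 500, a 3.46 hr
half-life against 3.5, and a regression slope of 1.37 hr with 95% CI
0.96–1.78 around a generating slope of 1.5).

A thin CLI mirrors the library (`ck1switch switch-survey|efficiency|
decay|regress|conservation|run`); `run` drives the full pipeline from a
YAML config.

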