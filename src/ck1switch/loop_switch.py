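"""Two-distance activation-loop conformation metric and surveys.

The position of L173 in the CK1δ activation loop reports on the loop's
conformational state: the distance from L173 CD2 to L152 CD2 is short in
the "loop up" conformation and long in "loop down", while the distance
from L173 CD2 to the Y225 hydroxyl behaves oppositely. Comparing the two
distances with an indeterminate margin classifies each chain or frame
without any absolute threshold, which also transfers to CK1 homologs when
equivalent probe residues are supplied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .structures import Ensemble, Structure

__all__ = [
    "PROBE_RESIDUES",
    "SwitchMeasurement",
    "SwitchSurvey",
    "MissingProbeAtomError",
    "measure_switch_distances",
    "classify_conformation",
    "survey_structures",
    "survey_ensemble",
]

logger = logging.getLogger(__name__)

#: Default probe atoms (author numbering in CK1δ ΔC).
PROBE_RESIDUES: dict[str, tuple[int, str]] = {
    "mobile": (173, "CD2"),  # L173, translocates with the loop
    "site_up": (152, "CD2"),  # L152, close in "loop up"
    "site_down": (225, "OH"),  # Y225, close in "loop down"
}

UP = "up"
DOWN = "down"
INDETERMINATE = "indeterminate"


class MissingProbeAtomError(ValueError):
    """A probe atom is absent (e.g. disordered side chain not modelled)."""


@dataclass(frozen=True)
class SwitchMeasurement:
    """The two probe distances and (optionally) a conformation label."""

    source_id: str
    chain: str
    d_L152: float  # Å, L173 CD2 ↔ L152 CD2
    d_Y225: float  # Å, L173 CD2 ↔ Y225 OH
    frame: int | None = None
    label: str | None = None


@dataclass
class SwitchSurvey:
    """Rows of switch measurements plus per-label counts and a skip list."""

    rows: list[SwitchMeasurement]
    skipped: list[str]

    @property
    def counts(self) -> dict[str, int]:
        out = {UP: 0, DOWN: 0, INDETERMINATE: 0}
        for r in self.rows:
            out[r.label] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        """Scatter table (one row per chain/frame) for CSV export."""
        return pd.DataFrame(
            {
                "source_id": [r.source_id for r in self.rows],
                "chain": [r.chain for r in self.rows],
                "frame": [r.frame for r in self.rows],
                "d_L152_A": [r.d_L152 for r in self.rows],
                "d_Y225_A": [r.d_Y225 for r in self.rows],
                "label": [r.label for r in self.rows],
            }
        )


def measure_switch_distances(
    structure: Structure,
    chain: str,
    probe_residues: dict[str, tuple[int, str]] | None = None,
) -> SwitchMeasurement:
    """Measure the two activation-loop probe distances in one chain.

    Raises :class:`MissingProbeAtomError` naming the residue/atom if any
    probe atom is absent after altloc resolution.
    """
    probes = probe_residues or PROBE_RESIDUES
    coords = {}
    for key in ("mobile", "site_up", "site_down"):
        res_seq, atom_name = probes[key]
        atom = structure.find_atom(chain, res_seq, atom_name)
        if atom is None:
            raise MissingProbeAtomError(
                f"{structure.id} chain {chain}: missing probe atom "
                f"{atom_name} of residue {res_seq}"
            )
        coords[key] = np.asarray(atom.xyz)
    d_l152 = float(np.linalg.norm(coords["mobile"] - coords["site_up"]))
    d_y225 = float(np.linalg.norm(coords["mobile"] - coords["site_down"]))
    return SwitchMeasurement(
        source_id=structure.id, chain=chain, d_L152=d_l152, d_Y225=d_y225
    )


def classify_conformation(m: SwitchMeasurement, margin: float = 1.0) -> SwitchMeasurement:
    """Label a measurement as "up", "down" or "indeterminate".

    up:   d_L152 < d_Y225 − margin   (L173 packed against L152)
    down: d_Y225 < d_L152 − margin   (L173 packed against Y225)
    otherwise indeterminate. The rule is symmetric: swapping the two
    distances swaps up ↔ down.
    """
    if m.d_L152 < m.d_Y225 - margin:
        label = UP
    elif m.d_Y225 < m.d_L152 - margin:
        label = DOWN
    else:
        label = INDETERMINATE
    return replace(m, label=label)


def survey_structures(
    entries: list[tuple[Structure, list[str] | None]],
    margin: float = 1.0,
    probe_residues: dict[str, tuple[int, str]] | None = None,
) -> SwitchSurvey:
    """Classify every requested chain of every structure.

    ``entries`` pairs each structure with a chain list (``None`` = all
    chains). Chains missing a probe atom are skipped with a warning and
    recorded in the survey's skip list rather than silently dropped.
    """
    if not entries:
        raise ValueError("empty survey input")
    rows: list[SwitchMeasurement] = []
    skipped: list[str] = []
    for structure, chains in entries:
        for chain in chains if chains is not None else structure.chains():
            try:
                m = measure_switch_distances(structure, chain, probe_residues)
            except MissingProbeAtomError as exc:
                logger.warning("skipping %s", exc)
                skipped.append(f"{structure.id}:{chain}")
                continue
            rows.append(classify_conformation(m, margin))
    return SwitchSurvey(rows=rows, skipped=skipped)


def survey_ensemble(
    ensemble: Ensemble,
    margin: float = 1.0,
    chain: str | None = None,
    probe_residues: dict[str, tuple[int, str]] | None = None,
) -> SwitchSurvey:
    """Classify every frame of an ensemble (one chain per frame)."""
    if ensemble.n_frames == 0:
        raise ValueError("empty ensemble")
    if chain is None:
        chains = ensemble.topology.chains()
        chain = chains[0]
    rows: list[SwitchMeasurement] = []
    skipped: list[str] = []
    for i in range(ensemble.n_frames):
        frame = ensemble.frame_structure(i)
        try:
            m = measure_switch_distances(frame, chain, probe_residues)
        except MissingProbeAtomError as exc:
            logger.warning("skipping %s", exc)
            skipped.append(f"{frame.id}:{chain}")
            continue
        m = replace(m, frame=i)
        rows.append(classify_conformation(m, margin))
    return SwitchSurvey(rows=rows, skipped=skipped)
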