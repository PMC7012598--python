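"""Structure, ensemble and selection containers with PDB/mmCIF I/O.

Coordinates are stored in Å. Author residue numbering is authoritative
throughout (CK1δ ΔC is numbered 1–317, so L152, L173, Y225 and the loop
segments 168–175 / 213–224 refer to author numbers); no renumbering is
ever applied. Reading goes through :mod:`gemmi`, which handles both PDB
v3.3 and mmCIF; for mmCIF files chains are identified by ``auth_asym_id``
to match the crystallographic chain A/B language.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "Ensemble",
    "AtomSelection",
    "read_structure",
    "write_structure",
    "read_ensemble",
    "select_atoms",
    "strip_nonprotein",
    "STANDARD_AMINO_ACIDS",
]

#: Three-letter codes treated as protein when stripping non-protein residues.
#: Selenomethionine is kept because it substitutes for MET in crystal structures.
STANDARD_AMINO_ACIDS = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO
       SER THR TRP TYR VAL MSE""".split()
)

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})


class StructureError(ValueError):
    """Raised for malformed structures, topologies or selections."""


@dataclass(frozen=True)
class Atom:
    """One atom record (author numbering, Å coordinates)."""

    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain: str
    altloc: str
    occupancy: float
    xyz: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in self.xyz):
            raise StructureError(f"non-finite coordinates for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise StructureError(
                f"occupancy {self.occupancy} outside [0, 1] for atom {self.name}"
            )

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Structure:
    """An ordered collection of atoms from one model."""

    id: str
    atoms: list[Atom]
    source_format: str = "PDB"

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) float array of coordinates in Å."""
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray, id: str | None = None) -> "Structure":
        """Copy of this structure with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise StructureError(
                f"coordinate shape {coords.shape} does not match atom count {len(self.atoms)}"
            )
        atoms = [
            replace(a, xyz=tuple(float(v) for v in c))
            for a, c in zip(self.atoms, coords)
        ]
        return Structure(id=id or self.id, atoms=atoms, source_format=self.source_format)

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain, None)
        return list(seen)

    def find_atom(self, chain: str, res_seq: int, name: str) -> Atom | None:
        for a in self.atoms:
            if a.chain == chain and a.res_seq == res_seq and a.name == name:
                return a
        return None

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass
class Ensemble:
    """Frames over a fixed topology (one coordinate set per topology atom)."""

    topology: Structure
    frames: list[np.ndarray]
    frame_times: list[float] | None = None  # ns

    def __post_init__(self) -> None:
        n = len(self.topology.atoms)
        for i, f in enumerate(self.frames):
            f = np.asarray(f, dtype=float)
            if f.shape != (n, 3):
                raise StructureError(
                    f"frame {i} has shape {f.shape}, topology has {n} atoms"
                )
            self.frames[i] = f
        if self.frame_times is not None:
            if len(self.frame_times) != len(self.frames):
                raise StructureError("frame_times length does not match frame count")
            diffs = np.diff(self.frame_times)
            if len(diffs) and not np.all(diffs > 0):
                raise StructureError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def frame_structure(self, i: int) -> Structure:
        return self.topology.with_coords(self.frames[i], id=f"{self.topology.id}:frame{i}")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class AtomSelection:
    """Chain / author-residue-range / atom-name selection.

    Any field left as ``None`` (or an empty ``atom_names``) matches everything,
    so ``AtomSelection()`` selects all atoms.
    """

    chain: str | None = None
    res_range: tuple[int, int] | None = None
    atom_names: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.res_range is not None and self.res_range[0] > self.res_range[1]:
            raise StructureError(f"residue range {self.res_range} has start > end")
        object.__setattr__(self, "atom_names", frozenset(self.atom_names))

    def matches(self, atom: Atom) -> bool:
        if self.chain is not None and atom.chain != self.chain:
            return False
        if self.res_range is not None and not (
            self.res_range[0] <= atom.res_seq <= self.res_range[1]
        ):
            return False
        if self.atom_names and atom.name not in self.atom_names:
            return False
        return True


def backbone_selection(res_range: tuple[int, int] | None = None,
                       chain: str | None = None) -> AtomSelection:
    """Heavy-backbone (N, CA, C, O) selection for a residue range."""
    return AtomSelection(chain=chain, res_range=res_range, atom_names=BACKBONE_ATOMS)


# ---------------------------------------------------------------------------
# reading


def _gemmi_to_structure(st: gemmi.Structure, struct_id: str, fmt: str) -> Structure:
    """Flatten the first model; resolve altlocs to one conformer per atom.

    Altloc policy: keep the highest-occupancy conformer, breaking ties in
    favour of altloc "A" (then alphabetical), which is the common convention.
    """
    st.setup_entities()
    if len(st) == 0:
        raise StructureError(f"{struct_id}: file contains no models")
    model = st[0]
    atoms: list[Atom] = []
    serial = 0
    for chain in model:
        for residue in chain:
            # group altloc variants of the same atom name
            by_name: dict[str, list[gemmi.Atom]] = {}
            for at in residue:
                by_name.setdefault(at.name, []).append(at)
            for name, variants in by_name.items():
                if len(variants) == 1:
                    chosen = variants[0]
                else:
                    chosen = sorted(
                        variants, key=lambda a: (-a.occ, a.altloc or "A")
                    )[0]
                serial += 1
                atoms.append(
                    Atom(
                        serial=serial,
                        name=name,
                        element=chosen.element.name,
                        res_name=residue.name,
                        res_seq=residue.seqid.num,
                        chain=chain.name,
                        altloc=chosen.altloc or "",
                        occupancy=min(max(chosen.occ, 0.0), 1.0),
                        xyz=(chosen.pos.x, chosen.pos.y, chosen.pos.z),
                    )
                )
    return Structure(id=struct_id, atoms=atoms, source_format=fmt)


def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".cif", ".mmcif"):
        return "mmCIF"
    if suffix in (".pdb", ".ent"):
        return "PDB"
    head = path.read_text(errors="replace")[:2048]
    if head.lstrip().startswith("data_") or "_atom_site." in head:
        return "mmCIF"
    return "PDB"


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a single-model structure from a PDB or mmCIF file.

    Waters and ions are retained (use :func:`strip_nonprotein` to remove
    them); altlocs are resolved to the highest-occupancy conformer.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = _detect_format(path)
    try:
        if format == "PDB":
            st = gemmi.read_pdb(str(path))
        elif format == "mmCIF":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise StructureError(f"unknown structure format: {format!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path} as {format}: {exc}") from exc
    return _gemmi_to_structure(st, struct_id=path.stem, fmt=format)


def _structure_to_gemmi(structure: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.id
    model = gemmi.Model("1")
    chain_map: dict[str, gemmi.Chain] = {}
    for a in structure.atoms:
        chain = chain_map.get(a.chain)
        if chain is None:
            model.add_chain(gemmi.Chain(a.chain))
            chain = model[-1]  # gemmi copies on add; keep the stored one
            chain_map[a.chain] = chain
        res = None
        if len(chain) > 0:
            last = chain[-1]
            if last.seqid.num == a.res_seq and last.name == a.res_name:
                res = last
        if res is None:
            res = gemmi.Residue()
            res.name = a.res_name
            res.seqid = gemmi.SeqId(a.res_seq, " ")
            chain.add_residue(res)
            res = chain[-1]
        at = gemmi.Atom()
        at.name = a.name
        at.element = gemmi.Element(a.element)
        at.altloc = a.altloc[:1] if a.altloc else "\0"
        at.occ = a.occupancy
        at.pos = gemmi.Position(*a.xyz)
        res.add_atom(at)
    st.add_model(model)
    return st


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a structure as PDB (Å coordinates, author numbering)."""
    st = _structure_to_gemmi(structure)
    st.setup_entities()
    st.write_pdb(str(Path(path)))


def write_ensemble(ensemble: Ensemble, path: str | Path) -> None:
    """Write an ensemble as a multi-model PDB file."""
    st = gemmi.Structure()
    st.name = ensemble.topology.id
    for i in range(ensemble.n_frames):
        frame = ensemble.frame_structure(i)
        model_st = _structure_to_gemmi(frame)
        model = model_st[0]
        model.num = i + 1
        st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(Path(path)))


def _topology_key(atoms: Sequence[Atom]) -> list[tuple[str, int, str]]:
    return [(a.chain, a.res_seq, a.name) for a in atoms]


def read_ensemble(paths: str | Path | Iterable[str | Path],
                  format: str = "auto") -> Ensemble:
    """Read an ensemble from a multi-model file or a list of per-frame files.

    All frames must share one topology (atom count and identities); the
    first mismatching atom is named in the error.
    """
    if isinstance(paths, (str, Path)):
        path = Path(paths)
        fmt = _detect_format(path) if format == "auto" else format
        if fmt == "PDB":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        if len(st) == 0:
            raise StructureError(f"{path}: no models found")
        structures = []
        for i in range(len(st)):
            sub = gemmi.Structure()
            sub.add_model(st[i])
            structures.append(_gemmi_to_structure(sub, f"{path.stem}:model{i + 1}", fmt))
    else:
        structures = [read_structure(p, format=format) for p in paths]
    if not structures:
        raise StructureError("no frames given")

    topo = structures[0]
    ref_key = _topology_key(topo.atoms)
    frames = [topo.coords]
    for s in structures[1:]:
        key = _topology_key(s.atoms)
        if key != ref_key:
            if len(key) != len(ref_key):
                raise StructureError(
                    f"{s.id}: frame has {len(key)} atoms, topology has {len(ref_key)}"
                )
            for a, b in zip(ref_key, key):
                if a != b:
                    raise StructureError(
                        f"{s.id}: topology mismatch at atom {b} (expected {a})"
                    )
        frames.append(s.coords)
    return Ensemble(topology=topo, frames=frames)


def select_atoms(structure_or_topology: Structure, selection: AtomSelection) -> list[int]:
    """Indices (topology order) of atoms matched by ``selection``.

    An empty result is valid — e.g. selecting CD2 of a residue whose side
    chain was not modelled.
    """
    return [
        i for i, a in enumerate(structure_or_topology.atoms) if selection.matches(a)
    ]


def strip_nonprotein(obj: Structure | Ensemble) -> Structure | Ensemble:
    """Remove waters, counter-ions, sulfate/tungstate anions and all other
    non-amino-acid residues. Idempotent; frames are reduced consistently."""
    if isinstance(obj, Ensemble):
        keep = [
            i for i, a in enumerate(obj.topology.atoms)
            if a.res_name in STANDARD_AMINO_ACIDS
        ]
        atoms = [obj.topology.atoms[i] for i in keep]
        topo = Structure(id=obj.topology.id, atoms=atoms,
                         source_format=obj.topology.source_format)
        frames = [f[keep] for f in obj.frames]
        return Ensemble(topology=topo, frames=frames,
                        frame_times=obj.frame_times)
    atoms = [a for a in obj.atoms if a.res_name in STANDARD_AMINO_ACIDS]
    return Structure(id=obj.id, atoms=atoms, source_format=obj.source_format)
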