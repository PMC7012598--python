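"""Helpers for the deposited crystal structures used in the analysis.

The activation-loop switch analysis is anchored on deposited CK1δ
structures: 1CKJ (wild type, loop "up" in chain A and "down" in chain B)
and 6PXN (the tau mutant R178C, same chain assignment); 6PXO and 6PXP are
companion depositions. These helpers locate local copies (the analyses
themselves never touch the network) and, where a network is available,
can fetch entries from RCSB.
"""

from __future__ import annotations

import urllib.request
from pathlib import Path

from .structures import Structure, read_structure

__all__ = ["ACCESSIONS", "EXPECTED_CHAIN_LABELS", "find_local_structure", "fetch_pdb"]

#: Deposited entries referenced by the analysis.
ACCESSIONS = ("1CKJ", "6PXN", "6PXO", "6PXP", "5X17")

#: Activation-loop state of each chain in the two switch-defining entries.
EXPECTED_CHAIN_LABELS = {
    ("1CKJ", "A"): "up",
    ("1CKJ", "B"): "down",
    ("6PXN", "A"): "up",
    ("6PXN", "B"): "down",
}


def find_local_structure(pdb_id: str, search_dirs: list[str | Path]) -> Structure | None:
    """Read a locally stored copy of a PDB entry, if present.

    Looks for ``<id>.pdb``, ``<id>.ent``, ``<id>.cif`` (either case) in
    each directory; returns ``None`` when no copy is found.
    """
    names = [
        f"{pdb_id.lower()}{ext}" for ext in (".pdb", ".ent", ".cif")
    ] + [f"{pdb_id.upper()}{ext}" for ext in (".pdb", ".ent", ".cif")]
    for d in search_dirs:
        d = Path(d)
        for name in names:
            path = d / name
            if path.exists():
                structure = read_structure(path)
                structure.id = pdb_id.upper()
                return structure
    return None


def fetch_pdb(pdb_id: str, dest_dir: str | Path, timeout: float = 30.0) -> Path:
    """Download one PDB entry from RCSB (requires network access)."""
    dest_dir = Path(dest_dir)
    dest_dir.mkdir(parents=True, exist_ok=True)
    dest = dest_dir / f"{pdb_id.lower()}.pdb"
    url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
    with urllib.request.urlopen(url, timeout=timeout) as response:
        dest.write_bytes(response.read())
    return dest
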