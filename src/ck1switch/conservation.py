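"""Reference-anchored percent identity over an alignment patch.

Conservation of the surface patch linking the CK1 anion sites and the
substrate cleft is quantified per position as the percentage of aligned
sequences whose residue matches the reference sequence (CK1δ author
numbering); gaps count as mismatches, which is the conservative choice
for a conservation claim. This is match-to-reference identity, not column
consensus, because the claim is anchored on specific CK1δ positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import AlignIO

__all__ = ["AlignmentPatch", "patch_identity"]


@dataclass
class AlignmentPatch:
    """Per-position identity (%) over a set of reference positions."""

    reference_id: str
    n_sequences: int
    positions: list[int]  # author numbering in the ungapped reference
    per_position_identity: dict[int, float]  # position → % identity

    @property
    def min_identity(self) -> float:
        return min(self.per_position_identity.values())

    @property
    def mean_identity(self) -> float:
        vals = list(self.per_position_identity.values())
        return sum(vals) / len(vals)


def patch_identity(
    alignment_path: str | Path,
    reference_id: str,
    patch_positions: list[int],
    ref_offset: int = 0,
) -> AlignmentPatch:
    """Percent identity to the reference at each patch position.

    ``patch_positions`` are 1-based positions in the *ungapped* reference
    sequence, optionally shifted by ``ref_offset`` (author position =
    ungapped index + offset). Identity at a position is
    100 × (matching sequences) / (total sequences) — the reference itself
    counts as one of the sequences, and a gap in any sequence is a
    mismatch.
    """
    alignment = AlignIO.read(str(alignment_path), "fasta")
    ref_record = None
    for rec in alignment:
        if rec.id == reference_id:
            ref_record = rec
            break
    if ref_record is None:
        raise ValueError(f"reference {reference_id!r} not found in alignment")

    # map ungapped reference positions (1-based) to alignment columns
    col_of_pos: dict[int, int] = {}
    pos = 0
    for col, residue in enumerate(str(ref_record.seq)):
        if residue != "-":
            pos += 1
            col_of_pos[pos] = col

    n = len(alignment)
    identities: dict[int, float] = {}
    for author_pos in patch_positions:
        ungapped = author_pos - ref_offset
        if ungapped not in col_of_pos:
            raise IndexError(
                f"position {author_pos} (ungapped {ungapped}) is outside the "
                f"reference sequence (length {pos})"
            )
        col = col_of_pos[ungapped]
        ref_res = str(ref_record.seq[col]).upper()
        matches = sum(
            1 for rec in alignment if str(rec.seq[col]).upper() == ref_res
        )
        identities[author_pos] = 100.0 * matches / n

    return AlignmentPatch(
        reference_id=reference_id,
        n_sequences=n,
        positions=list(patch_positions),
        per_position_identity=identities,
    )
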