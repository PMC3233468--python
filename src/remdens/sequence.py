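"""Topology constants for the Abeta(12-28) peptide.

The peptide is the 17-residue fragment VHHQKLVFFAEDVGSNK of the amyloid-beta
peptide, numbered 12-28 as in the full-length Abeta(1-42) sequence.  Every
residue is represented by its five backbone atoms N, H, CA, C, O (no side
chains, no proline in the sequence, glycine keeps all five atoms), giving an
85-atom model.
"""

from __future__ import annotations

import numpy as np

SEQUENCE_ONE = "VHHQKLVFFAEDVGSNK"

FIRST_RESIDUE_ID = 12
LAST_RESIDUE_ID = 28

N_RESIDUES = len(SEQUENCE_ONE)  # 17
BACKBONE_ATOMS = ("N", "H", "CA", "C", "O")
ATOMS_PER_RESIDUE = len(BACKBONE_ATOMS)  # 5
N_ATOMS = N_RESIDUES * ATOMS_PER_RESIDUE  # 85

THREE_LETTER = {
    "A": "ALA", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "K": "LYS", "L": "LEU", "N": "ASN", "Q": "GLN",
    "S": "SER", "V": "VAL",
}

#: residue id -> one-letter code, e.g. 19 -> "F"
RESIDUE_ONE = {FIRST_RESIDUE_ID + i: aa for i, aa in enumerate(SEQUENCE_ONE)}

RESIDUE_IDS = np.arange(FIRST_RESIDUE_ID, LAST_RESIDUE_ID + 1)

GLYCINE_IDS = frozenset(rid for rid, aa in RESIDUE_ONE.items() if aa == "G")  # {25}

#: residues pooled for the Ramachandran statistics: 13-27 except glycine (G25)
DEFAULT_ANALYSIS_RESIDUES = tuple(
    rid for rid in range(13, 28) if rid not in GLYCINE_IDS
)

#: hydrophobic stretch L17-V18-F19-F20-A21 used for the SASA analysis
LVFFA_RESIDUES = (17, 18, 19, 20, 21)


def residue_index(residue_id: int) -> int:
    """0-based chain index of a residue id in the 12-28 numbering."""
    if not FIRST_RESIDUE_ID <= residue_id <= LAST_RESIDUE_ID:
        raise ValueError(f"residue id {residue_id} outside 12..28")
    return residue_id - FIRST_RESIDUE_ID


def atom_index(residue_id: int, atom_name: str) -> int:
    """Flat atom index of (residue id, backbone atom name) in the 85-atom layout."""
    if atom_name not in BACKBONE_ATOMS:
        raise ValueError(f"unknown backbone atom {atom_name!r}")
    return residue_index(residue_id) * ATOMS_PER_RESIDUE + BACKBONE_ATOMS.index(atom_name)
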