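"""Dihedral-only secondary-structure assignment (PROSS-style mesostates).

Each defined (phi, psi) pair is mapped to a coarse 60x60-degree mesostate
cell; runs of cells then yield one of five labels per residue:

* H (alpha-helix): run of >= 4 consecutive helical mesostates,
* E (beta-strand): run of >= 2 extended-beta mesostates,
* P (PPII):        run of >= 2 PPII mesostates not inside a helix,
* T (beta-turn):   the two central residues of a recognised four-residue
                   type-I' turn dihedral pattern,
* C (random coil): everything else, including residues whose torsions are
                   undefined (chain termini).

Precedence is H > E > P > T > C.  The mesostate grid uses phi boundaries at
+-30/+-90/+-150 and psi boundaries at multiples of 60, which places the
canonical helix (-63,-43), PPII (-75,145) and extended-beta (-120,130)
values in the interior of three distinct cells.  Turn patterns are matched
by +-40 degree boxes around the canonical type-I' pair (+60,+30)/(+90,0)
because (+90, 0) sits exactly on a phi grid line.  There is no hydrogen-bond
criterion anywhere: this is a pure torsion method.

The rule set is version-tagged; recovery tests use generator states matched
to this table, so results do not depend on reproducing any historical binary
bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rama import DihedralTable

RULE_VERSION = "mesostate-v1"

SS_LABELS = ("H", "P", "E", "T", "C")

HELIX_MIN_RUN = 4
STRAND_MIN_RUN = 2
PPII_MIN_RUN = 2

TURN_BOX_HALFWIDTH = 40.0
TURN1_CENTER = (60.0, 30.0)
TURN2_CENTER = (90.0, 0.0)


@dataclass
class SSAssignment:
    """Per-frame, per-residue labels from {H, P, E, T, C}."""

    labels: np.ndarray  # (n_frames, n_residues) of single characters
    residue_ids: np.ndarray
    defined: np.ndarray  # False at chain termini (no torsion pair)
    rule_version: str = RULE_VERSION

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]


def _in_cell(phi, psi, phi_center, psi_center):
    """Membership of the 60x60 mesostate cell centred on (phi_center, psi_center)."""
    dphi = np.abs((phi - phi_center + 180.0) % 360.0 - 180.0)
    dpsi = np.abs((psi - psi_center + 180.0) % 360.0 - 180.0)
    return (dphi < 30.0) & (dpsi < 30.0)


def _in_box(phi, psi, center, half):
    dphi = np.abs((phi - center[0] + 180.0) % 360.0 - 180.0)
    dpsi = np.abs((psi - center[1] + 180.0) % 360.0 - 180.0)
    return (dphi < half) & (dpsi < half)


def _runs_of_at_least(mask: np.ndarray, min_run: int) -> np.ndarray:
    """True where a position belongs to a run of >= min_run consecutive Trues
    along the last axis."""
    if mask.shape[-1] < min_run:
        return np.zeros_like(mask)
    windows = np.lib.stride_tricks.sliding_window_view(mask, min_run, axis=-1)
    full = windows.all(axis=-1)  # window starting at each position is all-True
    out = np.zeros_like(mask)
    for start in range(full.shape[-1]):
        sel = full[..., start]
        out[sel, start:start + min_run] = True
    return out


def assign_ss(table: DihedralTable) -> SSAssignment:
    """Assign five-class secondary structure to every frame of a table."""
    table.validate()
    phi, psi = table.phi, table.psi
    defined = ~table.mask
    # mesostate membership (False wherever undefined)
    phi_f = np.where(defined, phi, 999.0)
    psi_f = np.where(defined, psi, 999.0)
    helix = _in_cell(phi_f, psi_f, -60.0, -30.0)
    ppii = _in_cell(phi_f, psi_f, -60.0, 150.0)
    strand = _in_cell(phi_f, psi_f, -120.0, 150.0)
    turn1 = _in_box(phi_f, psi_f, TURN1_CENTER, TURN_BOX_HALFWIDTH)
    turn2 = _in_box(phi_f, psi_f, TURN2_CENTER, TURN_BOX_HALFWIDTH)

    labels = np.full(phi.shape, "C", dtype="<U1")
    h_mask = _runs_of_at_least(helix, HELIX_MIN_RUN)
    e_mask = _runs_of_at_least(strand, STRAND_MIN_RUN)
    p_mask = _runs_of_at_least(ppii, PPII_MIN_RUN)
    # four-residue turn pattern: positions i..i+3 with (i+1, i+2) in the
    # type-I' boxes; the two central residues are labelled T
    t_mask = np.zeros_like(helix)
    if phi.shape[-1] >= 4:
        centre1 = turn1[:, 1:-2] & turn2[:, 2:-1]
        t_mask[:, 1:-2] |= centre1
        t_mask[:, 2:-1] |= centre1
    # precedence H > E > P > T > C, last write wins in reverse order
    labels[t_mask] = "T"
    labels[p_mask] = "P"
    labels[e_mask] = "E"
    labels[h_mask] = "H"
    labels[~defined] = "C"
    return SSAssignment(labels, table.residue_ids, defined)


def residue_propensities(assignment: SSAssignment) -> dict[str, np.ndarray]:
    """Per-residue fraction of each label over frames; fractions sum to 1."""
    out = {}
    n = assignment.labels.shape[0]
    for lab in SS_LABELS:
        out[lab] = (assignment.labels == lab).sum(axis=0) / n
    return out


def total_propensities(assignment: SSAssignment, defined_only: bool = True
                       ) -> dict[str, float]:
    """Overall fraction of each label.

    By default only residues whose torsion pair is defined contribute: a
    dihedral-only method cannot assign the chain termini, and counting their
    forced coil padding would bias the totals.  The result equals the
    residue-propensity average weighted by (defined) residue count.
    """
    labels = assignment.labels
    if defined_only:
        keep = assignment.defined.all(axis=0)
        labels = labels[:, keep]
    total = labels.size
    if total == 0:
        raise ValueError("no defined residues to total over")
    return {lab: float((labels == lab).sum() / total) for lab in SS_LABELS}
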