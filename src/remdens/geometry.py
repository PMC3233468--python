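"""Coordinate kernels shared by every analysis stage.

All coordinates are in nanometres, all angles in degrees on the half-open
interval [-180, 180).  The kernels are:

* torsion angles (IUPAC sign convention),
* backbone (phi, psi) extraction,
* sequential natural-extension (NeRF-style) backbone construction from
  internal coordinates,
* optimal rigid superposition (Kabsch, SVD with reflection guard) and
  C-alpha RMSD,
* numerical solvent-accessible surface area (Shrake-Rupley with a
  deterministic golden-spiral sphere mesh).

Only the five backbone atoms N, H, CA, C, O per residue are modelled; side
chains are out of scope, so absolute SASA values describe the backbone model,
not a full peptide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import sequence as seqmod
from .sequence import ATOMS_PER_RESIDUE, BACKBONE_ATOMS


class GeometryError(ValueError):
    """Raised for degenerate geometric input (colinear torsion atoms, ...)."""


# ---------------------------------------------------------------------------
# canonical internal coordinates (Engh-Huber-like), nm and degrees
# ---------------------------------------------------------------------------

BOND_N_CA = 0.1458
BOND_CA_C = 0.1525
BOND_C_N = 0.1329
BOND_C_O = 0.1231
BOND_N_H = 0.1010

ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_C_N_H = 119.3
ANGLE_CA_N_H = 118.2  # first residue only (no preceding carbonyl)

#: united-atom van der Waals radii used for SASA, nm
SASA_RADII = {"N": 0.155, "H": 0.110, "CA": 0.170, "C": 0.170, "O": 0.152}
SASA_PROBE = 0.14
SASA_N_POINTS = 960


def wrap_angle(angle):
    """Map angles (degrees) onto the half-open interval [-180, 180)."""
    return ((np.asarray(angle) + 180.0) % 360.0) - 180.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Conformation:
    """A single backbone conformation (85 atoms for the 17-residue peptide)."""

    coords: np.ndarray  # (n_atoms, 3) nm
    atom_names: np.ndarray  # (n_atoms,) str
    residue_ids: np.ndarray  # (n_atoms,) int
    residue_names: np.ndarray  # (n_atoms,) 3-letter str

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.atom_names = np.asarray(self.atom_names)
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.residue_names = np.asarray(self.residue_names)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def unique_residue_ids(self) -> np.ndarray:
        # preserves chain order (ids are contiguous ascending by construction)
        return np.unique(self.residue_ids)

    def validate(self) -> None:
        if self.coords.shape != (self.n_atoms, 3) or not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be a finite (n_atoms, 3) array")
        res_ids = self.unique_residue_ids
        if self.n_atoms != ATOMS_PER_RESIDUE * len(res_ids):
            raise ValueError("expected exactly 5 backbone atoms per residue")
        for rid in res_ids:
            names = self.atom_names[self.residue_ids == rid]
            if sorted(names) != sorted(BACKBONE_ATOMS):
                raise ValueError(f"residue {rid} lacks a complete N,H,CA,C,O set")

    def atom(self, residue_id: int, atom_name: str) -> np.ndarray:
        """Coordinates of one named atom, e.g. ``atom(22, "H")``."""
        sel = (self.residue_ids == residue_id) & (self.atom_names == atom_name)
        idx = np.flatnonzero(sel)
        if idx.size != 1:
            raise KeyError(f"atom {atom_name} of residue {residue_id} not present")
        return self.coords[idx[0]]

    def ca_coords(self) -> np.ndarray:
        return self.coords[self.atom_names == "CA"]


@dataclass
class InternalCoordinates:
    """Per-residue backbone torsions; phi[0] and psi[-1] are NaN (undefined); trans omega is stored as -180 under the half-open convention."""

    phi: np.ndarray
    psi: np.ndarray
    omega: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        if self.omega is None:
            self.omega = np.full_like(self.phi, -180.0)
        else:
            self.omega = np.asarray(self.omega, dtype=float)

    @property
    def n_residues(self) -> int:
        return self.phi.shape[0]

    def validate(self) -> None:
        for name, arr in (("phi", self.phi), ("psi", self.psi), ("omega", self.omega)):
            defined = arr[np.isfinite(arr)]
            if np.any(defined < -180.0) or np.any(defined >= 180.0):
                raise ValueError(f"{name} angles must lie in [-180, 180)")
        if not np.isnan(self.phi[0]) or not np.isnan(self.psi[-1]):
            raise ValueError("phi of the first and psi of the last residue are undefined")


# ---------------------------------------------------------------------------
# torsions
# ---------------------------------------------------------------------------


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Torsion angle of four points, degrees in [-180, 180), IUPAC sign.

    The sign is positive when, looking from p2 towards p3, the bond p3-p4
    is rotated clockwise relative to p1-p2.  A trans-planar arrangement is
    reported as -180 under the half-open convention; cis is 0.
    """
    return float(_dihedral_batch(*(np.asarray(p, float) for p in (p1, p2, p3, p4))))


def _dihedral_batch(p1, p2, p3, p4) -> np.ndarray:
    """Vectorised torsion over leading batch dimensions."""
    b0 = p1 - p2
    b1 = p3 - p2
    b2 = p4 - p3
    n1 = np.linalg.norm(b1, axis=-1)
    if np.any(n1 < 1e-12):
        raise GeometryError("zero-length central bond in torsion")
    b1u = b1 / n1[..., None]
    v = b0 - np.sum(b0 * b1u, axis=-1, keepdims=True) * b1u
    w = b2 - np.sum(b2 * b1u, axis=-1, keepdims=True) * b1u
    if np.any(np.linalg.norm(v, axis=-1) < 1e-9) or np.any(np.linalg.norm(w, axis=-1) < 1e-9):
        raise GeometryError("colinear atoms give an undefined torsion")
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1u, v) * w, axis=-1)
    return wrap_angle(np.degrees(np.arctan2(y, x)))


# ---------------------------------------------------------------------------
# phi / psi extraction
# ---------------------------------------------------------------------------


def _backbone_slices(n_res: int):
    """Flat indices of N, CA, C per residue in the 5-atoms-per-residue layout."""
    base = np.arange(n_res) * ATOMS_PER_RESIDUE
    return base + 0, base + 2, base + 3  # N, CA, C


def phi_psi_from_coords(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched (phi, psi) from stacked coordinates (..., n_atoms, 3).

    phi(i) is the torsion C(i-1)-N(i)-CA(i)-C(i), psi(i) the torsion
    N(i)-CA(i)-C(i)-N(i+1).  Terminal entries without a neighbour residue
    are NaN, never zero-filled.
    """
    coords = np.asarray(coords, dtype=float)
    n_res = coords.shape[-2] // ATOMS_PER_RESIDUE
    i_n, i_ca, i_c = _backbone_slices(n_res)
    N = coords[..., i_n, :]
    CA = coords[..., i_ca, :]
    C = coords[..., i_c, :]
    shape = coords.shape[:-2] + (n_res,)
    phi = np.full(shape, np.nan)
    psi = np.full(shape, np.nan)
    phi[..., 1:] = _dihedral_batch(C[..., :-1, :], N[..., 1:, :], CA[..., 1:, :], C[..., 1:, :])
    psi[..., :-1] = _dihedral_batch(N[..., :-1, :], CA[..., :-1, :], C[..., :-1, :], N[..., 1:, :])
    return phi, psi


def compute_phi_psi(conf: Conformation) -> InternalCoordinates:
    """Backbone torsions of one conformation; termini flagged NaN."""
    conf.validate()
    phi, psi = phi_psi_from_coords(conf.coords)
    return InternalCoordinates(phi=phi, psi=psi)


# ---------------------------------------------------------------------------
# backbone construction (sequential natural extension)
# ---------------------------------------------------------------------------


def _extend(a, b, c, bond: float, angle_deg: float, torsion_deg) -> np.ndarray:
    """Place atom d with |cd| = bond, angle(b,c,d) = angle and
    torsion(a,b,c,d) = torsion.  Batched over leading dimensions."""
    theta = np.radians(angle_deg)
    chi = np.radians(np.asarray(torsion_deg, dtype=float))
    bc = c - b
    bc /= np.linalg.norm(bc, axis=-1, keepdims=True)
    ab = b - a
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n, axis=-1, keepdims=True)
    if np.any(norm < 1e-12):
        raise GeometryError("colinear reference atoms in extension step")
    n /= norm
    m = np.cross(n, bc)
    d = (
        c
        - bond * np.cos(theta) * bc
        + bond * np.sin(theta) * (np.cos(chi)[..., None] * m + np.sin(chi)[..., None] * n)
    )
    return d


def build_backbone_batch(phi: np.ndarray, psi: np.ndarray, omega: np.ndarray | None = None) -> np.ndarray:
    """Build stacked backbone coordinates from torsion arrays.

    Parameters are (n_frames, n_res) arrays in degrees; phi[:, 0] and
    psi[:, -1] may be NaN (they do not influence any placement except the
    final carbonyl oxygen, which then defaults to the trans direction).
    Returns coordinates of shape (n_frames, n_res * 5, 3) in nm.
    """
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    psi = np.atleast_2d(np.asarray(psi, dtype=float))
    if omega is None:
        omega = np.full_like(phi, -180.0)
    else:
        omega = np.atleast_2d(np.asarray(omega, dtype=float))
    n_frames, n_res = phi.shape
    defined = {
        "phi": np.isfinite(phi[:, 1:]),
        "psi": np.isfinite(psi[:, :-1]),
    }
    for name, mask in defined.items():
        if not mask.all():
            raise GeometryError(f"{name} must be defined for all non-terminal residues")
    for name, arr in (("phi", phi[:, 1:]), ("psi", psi[:, :-1]), ("omega", omega)):
        if np.any(arr < -180.0) or np.any(arr >= 180.0):
            raise GeometryError(f"{name} out of [-180, 180)")

    coords = np.empty((n_frames, n_res * ATOMS_PER_RESIDUE, 3))
    i_n, i_ca, i_c = _backbone_slices(n_res)
    i_h = np.arange(n_res) * ATOMS_PER_RESIDUE + 1
    i_o = np.arange(n_res) * ATOMS_PER_RESIDUE + 4

    # first residue in a canonical frame
    N0 = np.zeros((n_frames, 3))
    CA0 = np.tile([BOND_N_CA, 0.0, 0.0], (n_frames, 1))
    th = np.radians(ANGLE_N_CA_C)
    C0 = CA0 + BOND_CA_C * np.stack(
        [np.full(n_frames, -np.cos(th)), np.full(n_frames, np.sin(th)), np.zeros(n_frames)],
        axis=-1,
    )
    coords[:, i_n[0]] = N0
    coords[:, i_ca[0]] = CA0
    coords[:, i_c[0]] = C0
    # amide H of the first residue: no preceding carbonyl; anti to C along N-CA
    coords[:, i_h[0]] = _extend(C0, CA0, N0, BOND_N_H, ANGLE_CA_N_H, np.full(n_frames, 180.0))

    N_prev, CA_prev, C_prev = N0, CA0, C0
    for i in range(n_res - 1):
        psi_i = psi[:, i]
        # carbonyl O anti to the next amide N across the C(i) sp2 centre
        coords[:, i_o[i]] = _extend(
            N_prev, CA_prev, C_prev, BOND_C_O, ANGLE_CA_C_O, wrap_angle(psi_i + 180.0)
        )
        N_next = _extend(N_prev, CA_prev, C_prev, BOND_C_N, ANGLE_CA_C_N, psi_i)
        CA_next = _extend(CA_prev, C_prev, N_next, BOND_N_CA, ANGLE_C_N_CA, omega[:, i])
        C_next = _extend(C_prev, N_next, CA_next, BOND_CA_C, ANGLE_N_CA_C, phi[:, i + 1])
        # amide H in the peptide plane, anti to the carbonyl O
        coords[:, i_h[i + 1]] = _extend(
            coords[:, i_o[i]], C_prev, N_next, BOND_N_H, ANGLE_C_N_H, np.full(n_frames, 180.0)
        )
        coords[:, i_n[i + 1]] = N_next
        coords[:, i_ca[i + 1]] = CA_next
        coords[:, i_c[i + 1]] = C_next
        N_prev, CA_prev, C_prev = N_next, CA_next, C_next

    # final carbonyl O: psi undefined -> trans placement (torsion 0 from N)
    psi_last = psi[:, -1]
    torsion_o = np.where(np.isfinite(psi_last), wrap_angle(psi_last + 180.0), 0.0)
    coords[:, i_o[-1]] = _extend(N_prev, CA_prev, C_prev, BOND_C_O, ANGLE_CA_C_O, torsion_o)
    return coords


def default_topology(sequence: str = seqmod.SEQUENCE_ONE, first_id: int = seqmod.FIRST_RESIDUE_ID):
    """(atom_names, residue_ids, residue_names) arrays for a sequence."""
    n_res = len(sequence)
    atom_names = np.array(list(BACKBONE_ATOMS) * n_res)
    residue_ids = np.repeat(np.arange(first_id, first_id + n_res), ATOMS_PER_RESIDUE)
    residue_names = np.repeat([seqmod.THREE_LETTER[aa] for aa in sequence], ATOMS_PER_RESIDUE)
    return atom_names, residue_ids, residue_names


def build_backbone(ic: InternalCoordinates, sequence: str = seqmod.SEQUENCE_ONE,
                   first_id: int = seqmod.FIRST_RESIDUE_ID) -> Conformation:
    """Build a Conformation from internal coordinates.

    Round-trip contract: ``compute_phi_psi(build_backbone(ic))`` reproduces
    the defined torsions to better than 1e-4 degrees.
    """
    if ic.n_residues != len(sequence):
        raise ValueError("internal coordinates and sequence length disagree")
    ic.validate()
    coords = build_backbone_batch(ic.phi[None, :], ic.psi[None, :], ic.omega[None, :])[0]
    atom_names, residue_ids, residue_names = default_topology(sequence, first_id)
    conf = Conformation(coords, atom_names, residue_ids, residue_names)
    conf.validate()
    return conf


# ---------------------------------------------------------------------------
# superposition and RMSD
# ---------------------------------------------------------------------------


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray):
    """Optimal rigid superposition of two (n, 3) point sets.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference`` in the
    least-squares sense; the rotation is proper (det = +1).
    """
    A = np.asarray(mobile, dtype=float)
    B = np.asarray(reference, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("point sets must share an (n, 3) shape")
    if A.shape[0] < 3:
        raise ValueError("superposition needs at least 3 atoms")
    ca = A.mean(axis=0)
    cb = B.mean(axis=0)
    H = (A - ca).T @ (B - cb)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    diff = (A @ R.T + t) - B
    rmsd = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    return R, t, rmsd


def superpose_conformations(mobile: Conformation, reference: Conformation,
                            selection: Iterable[str] = ("CA",)):
    """Kabsch fit of named backbone atoms; returns (rotation, translation, rmsd)."""
    sel = set(selection)
    mask_m = np.isin(mobile.atom_names, list(sel))
    mask_r = np.isin(reference.atom_names, list(sel))
    return kabsch_superpose(mobile.coords[mask_m], reference.coords[mask_r])


def rmsd_ca(a, b) -> float:
    """Minimum C-alpha RMSD (nm) over rigid motions.

    Accepts Conformations or bare (n_ca, 3) coordinate arrays.
    """
    xa = a.ca_coords() if isinstance(a, Conformation) else np.asarray(a, float)
    xb = b.ca_coords() if isinstance(b, Conformation) else np.asarray(b, float)
    return kabsch_superpose(xa, xb)[2]


def pairwise_rmsd_matrix(ca_stack: np.ndarray, chunk: int = 200_000) -> np.ndarray:
    """Symmetric matrix of minimum C-alpha RMSDs for stacked CA coordinates.

    ``ca_stack`` is (n_frames, n_ca, 3).  Uses the singular values of the
    3x3 cross-covariance (via eigvalsh) instead of a per-pair SVD so that a
    few million pairs stay tractable.
    """
    X = np.asarray(ca_stack, dtype=float)
    n, n_ca, _ = X.shape
    Xc = X - X.mean(axis=1, keepdims=True)
    sq = np.einsum("nij,nij->n", Xc, Xc)
    out = np.zeros((n, n))
    ii, jj = np.triu_indices(n, k=1)
    for start in range(0, ii.size, chunk):
        i = ii[start:start + chunk]
        j = jj[start:start + chunk]
        H = np.einsum("pki,pkj->pij", Xc[i], Xc[j])
        det_sign = np.sign(np.linalg.det(H))
        det_sign[det_sign == 0] = 1.0
        evals = np.linalg.eigvalsh(np.einsum("pki,pkj->pij", H, H))
        s = np.sqrt(np.clip(evals, 0.0, None))  # ascending singular values
        trace_s = s[:, 2] + s[:, 1] + det_sign * s[:, 0]
        msd = np.clip(sq[i] + sq[j] - 2.0 * trace_s, 0.0, None) / n_ca
        out[i, j] = out[j, i] = np.sqrt(msd)
    return out


def rmsd_to_reference(ca_stack: np.ndarray, ref_ca: np.ndarray) -> np.ndarray:
    """Minimum C-alpha RMSD of every stacked frame to one reference."""
    X = np.asarray(ca_stack, dtype=float)
    R = np.asarray(ref_ca, dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    Rc = R - R.mean(axis=0)
    sq = np.einsum("nij,nij->n", Xc, Xc) + np.einsum("ij,ij->", Rc, Rc)
    H = np.einsum("nki,kj->nij", Xc, Rc)
    det_sign = np.sign(np.linalg.det(H))
    det_sign[det_sign == 0] = 1.0
    evals = np.linalg.eigvalsh(np.einsum("nki,nkj->nij", H, H))
    s = np.sqrt(np.clip(evals, 0.0, None))
    trace_s = s[:, 2] + s[:, 1] + det_sign * s[:, 0]
    msd = np.clip(sq - 2.0 * trace_s, 0.0, None) / X.shape[1]
    return np.sqrt(msd)


# ---------------------------------------------------------------------------
# solvent-accessible surface area
# ---------------------------------------------------------------------------


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere mesh (Fibonacci spiral)."""
    k = np.arange(n) + 0.5
    z = 1.0 - 2.0 * k / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    phi = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def shrake_rupley_sasa(conf, radii=None, probe: float = SASA_PROBE,
                       n_points: int = SASA_N_POINTS) -> np.ndarray:
    """Per-atom solvent-accessible surface area, nm^2.

    ``conf`` may be a Conformation or a bare (n_atoms, 3) array (then
    ``radii`` must be a per-atom array).  ``radii`` defaults to the
    united-atom set keyed by backbone atom name.
    """
    if isinstance(conf, Conformation):
        coords = conf.coords
        if radii is None:
            radii = np.array([SASA_RADII[a] for a in conf.atom_names])
    else:
        coords = np.asarray(conf, dtype=float)
        if radii is None:
            raise ValueError("per-atom radii are required for bare coordinates")
    radii = np.asarray(radii, dtype=float)
    if np.any(radii < 0):
        raise ValueError("atomic radii must be non-negative")
    if probe < 0:
        raise ValueError("probe radius must be non-negative")
    if n_points < 64:
        raise ValueError("need at least 64 sphere points")

    mesh = golden_spiral_points(n_points)
    n_atoms = coords.shape[0]
    expanded = radii + probe
    areas = np.empty(n_atoms)
    # neighbour cut: atom j can occlude i only within expanded_i + expanded_j
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
    for i in range(n_atoms):
        cut = (expanded[i] + expanded) ** 2
        nbr = np.flatnonzero((d2[i] < cut) & (np.arange(n_atoms) != i))
        pts = coords[i] + expanded[i] * mesh
        if nbr.size:
            dp = pts[:, None, :] - coords[nbr][None, :, :]
            buried = np.any(np.sum(dp * dp, axis=-1) < (expanded[nbr] ** 2)[None, :], axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * expanded[i] ** 2 * frac
    return areas


def residue_sasa(conf: Conformation, **kwargs) -> dict[int, float]:
    """Backbone SASA summed per residue id."""
    per_atom = shrake_rupley_sasa(conf, **kwargs)
    return {int(rid): float(per_atom[conf.residue_ids == rid].sum())
            for rid in conf.unique_residue_ids}
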