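"""Ramachandran-region statistics and potential-of-mean-force maps.

The (phi, psi) plane for phi < 0 is partitioned into three boxes:

* alpha region:  -180 <= phi < 0 and -120 <= psi < 30
* bridge region: -180 <= phi < 0 and   30 <= psi < 90
* beta region:   -180 <= phi < 0 and ( 90 <= psi < 180 or -180 <= psi < -120 )

Everything with phi >= 0 is "other".  Boundaries are half-open [lo, hi) so
the classifier is total; since sampled angles are continuous this differs
from strict inequalities only on a measure-zero set.  The three psi
intervals tile [-180, 180) exactly for phi < 0, which is why region
probabilities over phi < 0 plus the "other" mass sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fes import FESGrid, fes_2d, free_energy_from_counts
from .sequence import DEFAULT_ANALYSIS_RESIDUES

REGIONS = ("alpha", "bridge", "beta", "other")


@dataclass
class DihedralTable:
    """(phi, psi) in degrees per frame and residue, with an undefined mask."""

    phi: np.ndarray  # (n_frames, n_residues)
    psi: np.ndarray
    residue_ids: np.ndarray  # (n_residues,)
    mask: np.ndarray = None  # type: ignore[assignment]  # True where undefined

    def __post_init__(self):
        self.phi = np.atleast_2d(np.asarray(self.phi, dtype=float))
        self.psi = np.atleast_2d(np.asarray(self.psi, dtype=float))
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        if self.mask is None:
            self.mask = ~(np.isfinite(self.phi) & np.isfinite(self.psi))
        self.mask = np.atleast_2d(np.asarray(self.mask, dtype=bool))

    @property
    def n_frames(self) -> int:
        return self.phi.shape[0]

    def validate(self) -> None:
        defined_phi = self.phi[~self.mask]
        defined_psi = self.psi[~self.mask]
        for arr in (defined_phi, defined_psi):
            if np.any(arr < -180.0) or np.any(arr >= 180.0):
                raise ValueError("angles must lie in [-180, 180)")

    def select_residues(self, residue_filter) -> "DihedralTable":
        keep = np.isin(self.residue_ids, list(residue_filter))
        if not keep.any():
            raise ValueError("residue filter selects no residues")
        return DihedralTable(
            self.phi[:, keep], self.psi[:, keep], self.residue_ids[keep], self.mask[:, keep]
        )


@dataclass
class RegionProbabilities:
    p_alpha: float
    p_bridge: float
    p_beta: float
    p_other: float

    def as_dict(self) -> dict[str, float]:
        return {
            "alpha": self.p_alpha,
            "bridge": self.p_bridge,
            "beta": self.p_beta,
            "other": self.p_other,
        }

    def validate(self) -> None:
        vals = list(self.as_dict().values())
        if any(v < 0 or v > 1 for v in vals) or abs(sum(vals) - 1.0) > 1e-12:
            raise ValueError("region probabilities must sum to one")


def _check_range(phi, psi):
    for name, a in (("phi", phi), ("psi", psi)):
        if np.any(a < -180.0) or np.any(a >= 180.0):
            raise ValueError(f"{name} outside [-180, 180); no silent wrapping")


def classify_region(phi, psi):
    """Region label(s) for (phi, psi) in degrees.

    Scalar inputs return a string; array inputs an array of strings.
    """
    phi_a = np.asarray(phi, dtype=float)
    psi_a = np.asarray(psi, dtype=float)
    _check_range(phi_a, psi_a)
    out = np.full(phi_a.shape, "other", dtype="<U6")
    neg = phi_a < 0
    out[neg & (psi_a >= -120) & (psi_a < 30)] = "alpha"
    out[neg & (psi_a >= 30) & (psi_a < 90)] = "bridge"
    out[neg & ((psi_a >= 90) | (psi_a < -120))] = "beta"
    if np.isscalar(phi) or out.shape == ():
        return str(out)
    return out


def region_counts(table: DihedralTable, residue_filter=None) -> dict[str, int]:
    """Pooled region counts over defined entries of (optionally filtered) residues."""
    t = table if residue_filter is None else table.select_residues(residue_filter)
    t.validate()
    ok = ~t.mask
    labels = classify_region(t.phi[ok], t.psi[ok])
    return {r: int(np.sum(labels == r)) for r in REGIONS}


def region_probabilities(table: DihedralTable, residue_filter=DEFAULT_ANALYSIS_RESIDUES
                         ) -> RegionProbabilities:
    """Pooled region probabilities (counts / total defined entries).

    The default residue filter pools residues 13-27 excluding glycine
    (14 residues); pass ``residue_filter=None`` to use every residue in the
    table (e.g. for synthetic tables with their own numbering).
    """
    counts = region_counts(table, residue_filter)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no defined dihedral entries selected")
    rp = RegionProbabilities(*(counts[r] / total for r in REGIONS))
    rp.validate()
    return rp


def ramachandran_pmf(table: DihedralTable, temperature: float, bin_deg: float = 10.0,
                     residue_filter=None) -> FESGrid:
    """Potential of mean force over the (phi, psi) plane.

    ``bin_deg`` must divide 360 so the grid tiles the torus exactly.
    """
    if bin_deg <= 0 or abs(360.0 / bin_deg - round(360.0 / bin_deg)) > 1e-9:
        raise ValueError("bin_deg must divide 360")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    t = table if residue_filter is None else table.select_residues(residue_filter)
    t.validate()
    ok = ~t.mask
    edges = np.arange(-180.0, 180.0 + bin_deg / 2, bin_deg)
    counts, _, _ = np.histogram2d(t.phi[ok], t.psi[ok], bins=(edges, edges))
    grid = FESGrid(edges, edges, free_energy_from_counts(counts, temperature),
                   counts, temperature)
    grid.validate()
    return grid


@dataclass
class SplitHalfResult:
    differences: dict[str, float]  # per-region |delta p|
    converged: bool
    threshold: float


def split_half_comparison(table_a: DihedralTable, table_b: DihedralTable,
                          residue_filter=None, threshold: float = 0.02) -> SplitHalfResult:
    """Per-region absolute probability differences between two windows.

    Mirrors the convergence check of comparing region statistics from two
    non-overlapping stretches of the same simulation; the default 0.02
    threshold is the largest deviation regarded as converged.
    """
    pa = region_probabilities(table_a, residue_filter).as_dict()
    pb = region_probabilities(table_b, residue_filter).as_dict()
    diffs = {r: abs(pa[r] - pb[r]) for r in REGIONS}
    return SplitHalfResult(diffs, all(d <= threshold for d in diffs.values()), threshold)
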