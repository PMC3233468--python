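"""Synthetic conformational ensembles with controlled state populations.

No trajectories are deposited for the peptide, so every analysis stage is
exercised on ensembles generated here: equilibrium mixtures of coil, PPII,
helix, strand, turn and beta-hairpin conformers with user-set populations,
wrapped-Gaussian dihedral jitter and small Cartesian jitter.  Frames are
i.i.d. mixture draws, not a Markovian trajectory; there is no energetics,
solvent or kinetics.

Design notes

* The coil state draws every residue independently from the Ramachandran
  region mixture, so coil frames are mutually distant in C-alpha RMSD and
  connectivity clustering cannot bridge them into hairpin clusters.
* Intra-state spread is controlled by Cartesian noise (default 0.02 nm,
  which keeps pairs of same-state frames well below the 0.15 nm clustering
  cutoff); dihedral noise on a chain this long would be amplified by lever
  arms.
* True per-frame state labels are kept in the ensemble provenance for
  recovery tests; analysis stages never read them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import sequence as seqmod
from .geometry import (
    Conformation,
    build_backbone_batch,
    default_topology,
    phi_psi_from_coords,
    wrap_angle,
)
from .rama import DihedralTable

#: canonical per-state (phi, psi) literature values, degrees
DIHEDRAL_LIBRARY = {
    "helix": (-63.0, -43.0),
    "ppii": (-75.0, 145.0),
    "strand": (-120.0, 130.0),
    "turn1": (60.0, 30.0),   # type-I' turn, position i+1
    "turn2": (90.0, 0.0),    # type-I' turn, position i+2
}

#: default Ramachandran mixture for the coil state (alpha/bridge/beta/other)
DEFAULT_COIL_REGION_WEIGHTS = {"alpha": 0.26, "bridge": 0.06, "beta": 0.62, "other": 0.06}

DEFAULT_ANGULAR_NOISE_DEG = 4.0
DEFAULT_CARTESIAN_NOISE_NM = 0.02

HAIRPIN_DEFINITIONS = {
    # turn and strand residue ranges in the 12-28 numbering
    "hairpin1": {"turn": (19, 20, 21, 22), "strands": (tuple(range(14, 19)), tuple(range(23, 28)))},
    "hairpin2": {"turn": (17, 18, 19, 20), "strands": (tuple(range(13, 17)), tuple(range(21, 24)))},
}


@dataclass
class StateSpec:
    """One mixture component of a synthetic ensemble."""

    state: str
    weight: float
    dihedrals: np.ndarray | None = None  # (n_res, 2) per-residue means, or None
    region_weights: Mapping[str, float] | None = None  # coil-style mixture
    angular_noise_deg: float = DEFAULT_ANGULAR_NOISE_DEG
    cartesian_noise_nm: float = DEFAULT_CARTESIAN_NOISE_NM
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.dihedrals is not None:
            self.dihedrals = np.asarray(self.dihedrals, dtype=float)
        if self.angular_noise_deg < 0 or self.cartesian_noise_nm < 0:
            raise ValueError("noise widths must be non-negative")
        if (self.dihedrals is None) == (self.region_weights is None):
            raise ValueError("specify exactly one of dihedrals / region_weights")

    def with_weight(self, weight: float) -> "StateSpec":
        return StateSpec(self.state, weight, self.dihedrals, self.region_weights,
                         self.angular_noise_deg, self.cartesian_noise_nm, dict(self.metadata))


def validate_specs(specs: Sequence[StateSpec]) -> None:
    weights = np.array([s.weight for s in specs], dtype=float)
    if np.any(weights < 0):
        raise ValueError("state weights must be non-negative")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("state weights must sum to 1")


@dataclass
class Ensemble:
    """Ordered frames at one temperature with shared 85-atom topology."""

    coords: np.ndarray  # (n_frames, n_atoms, 3) nm
    atom_names: np.ndarray
    residue_ids: np.ndarray
    residue_names: np.ndarray
    temperature: float  # K
    frame_times: np.ndarray  # ps
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> Conformation:
        return Conformation(self.coords[i], self.atom_names, self.residue_ids, self.residue_names)

    def __iter__(self):
        return (self.frame(i) for i in range(self.n_frames))

    def ca_stack(self) -> np.ndarray:
        return self.coords[:, self.atom_names == "CA", :]

    def atom_series(self, residue_id: int, atom_name: str) -> np.ndarray:
        sel = (self.residue_ids == residue_id) & (self.atom_names == atom_name)
        idx = np.flatnonzero(sel)
        if idx.size != 1:
            raise KeyError(f"atom {atom_name} of residue {residue_id} not present")
        return self.coords[:, idx[0], :]

    def dihedral_table(self) -> DihedralTable:
        phi, psi = phi_psi_from_coords(self.coords)
        res_ids = self.residue_ids[self.atom_names == "CA"]
        return DihedralTable(wrap_nan(phi), wrap_nan(psi), res_ids)


def wrap_nan(angles: np.ndarray) -> np.ndarray:
    """wrap_angle that leaves NaN markers untouched."""
    out = np.asarray(angles, dtype=float).copy()
    ok = np.isfinite(out)
    out[ok] = wrap_angle(out[ok])
    return out


# ---------------------------------------------------------------------------
# region sampling
# ---------------------------------------------------------------------------


def _sample_region(region: str, size: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform (phi, psi) within one region box; (size, 2) degrees."""
    out = np.empty((size, 2))
    if region == "alpha":
        out[:, 0] = rng.uniform(-180.0, 0.0, size)
        out[:, 1] = rng.uniform(-120.0, 30.0, size)
    elif region == "bridge":
        out[:, 0] = rng.uniform(-180.0, 0.0, size)
        out[:, 1] = rng.uniform(30.0, 90.0, size)
    elif region == "beta":
        out[:, 0] = rng.uniform(-180.0, 0.0, size)
        u = rng.uniform(0.0, 150.0, size)  # 90..180 (width 90) then -180..-120 (width 60)
        out[:, 1] = np.where(u < 90.0, 90.0 + u, -180.0 + (u - 90.0))
    elif region == "other":
        out[:, 0] = rng.uniform(0.0, 180.0, size)
        out[:, 1] = rng.uniform(-180.0, 180.0, size)
    else:
        raise ValueError(f"unknown region {region!r}")
    # uniform draws may hit the excluded upper endpoint only with probability 0
    return wrap_angle(out)


def _region_mixture_draws(weights: Mapping[str, float], size: int,
                          rng: np.random.Generator) -> np.ndarray:
    names = list(weights)
    w = np.array([weights[n] for n in names], dtype=float)
    if np.any(w < 0):
        raise ValueError("region weights must be non-negative")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("region weights must sum to 1")
    choice = rng.choice(len(names), size=size, p=w)
    out = np.empty((size, 2))
    for k, name in enumerate(names):
        idx = np.flatnonzero(choice == k)
        if idx.size:
            out[idx] = _sample_region(name, idx.size, rng)
    return out


def sample_region_dihedrals(weights: Mapping[str, float], n_frames: int, n_residues: int,
                            seed: int, residue_ids=None) -> DihedralTable:
    """i.i.d. (phi, psi) pairs drawn region-first, then uniform in the box.

    The default residue ids are the pooled analysis set 13-27 minus glycine
    when ``n_residues`` matches it, otherwise 0..n-1.
    """
    if n_frames <= 0 or n_residues <= 0:
        raise ValueError("n_frames and n_residues must be positive")
    rng = np.random.default_rng(seed)
    draws = _region_mixture_draws(weights, n_frames * n_residues, rng)
    phi = draws[:, 0].reshape(n_frames, n_residues)
    psi = draws[:, 1].reshape(n_frames, n_residues)
    if residue_ids is None:
        if n_residues == len(seqmod.DEFAULT_ANALYSIS_RESIDUES):
            residue_ids = np.array(seqmod.DEFAULT_ANALYSIS_RESIDUES)
        else:
            residue_ids = np.arange(n_residues)
    return DihedralTable(phi, psi, residue_ids, np.zeros_like(phi, dtype=bool))


# ---------------------------------------------------------------------------
# state libraries
# ---------------------------------------------------------------------------


def uniform_state(name: str, weight: float, library_key: str | None = None,
                  n_res: int = seqmod.N_RESIDUES, **kwargs) -> StateSpec:
    """A state whose residues all sit at one canonical library value."""
    phi0, psi0 = DIHEDRAL_LIBRARY[library_key or name]
    dih = np.tile([phi0, psi0], (n_res, 1))
    return StateSpec(name, weight, dihedrals=dih, **kwargs)


def coil_state(weight: float, region_weights: Mapping[str, float] | None = None,
               **kwargs) -> StateSpec:
    """Per-residue region-mixture coil (mutually distant frames by design)."""
    return StateSpec("coil", weight, region_weights=dict(region_weights or DEFAULT_COIL_REGION_WEIGHTS),
                     **kwargs)


def turn_tiled_state(weight: float, n_res: int = seqmod.N_RESIDUES, **kwargs) -> StateSpec:
    """A state tiled with alternating type-I' turn dihedrals.

    Alternating (i+1, i+2) turn values make nearly every interior residue
    the centre of a recognised four-residue turn pattern, so the
    secondary-structure stage labels the frame as turn throughout.
    """
    dih = np.empty((n_res, 2))
    dih[0::2] = DIHEDRAL_LIBRARY["turn1"]
    dih[1::2] = DIHEDRAL_LIBRARY["turn2"]
    return StateSpec("turn", weight, dihedrals=dih, **kwargs)


def hairpin_dihedrals(name: str, n_res: int = seqmod.N_RESIDUES,
                      first_id: int = seqmod.FIRST_RESIDUE_ID) -> np.ndarray:
    """Per-residue (phi, psi) means of a beta-hairpin template.

    Strand residues take extended-beta values, the two central turn residues
    the canonical type-I' pair, the outer two turn residues and all remaining
    residues extended values (the 'coil' flanks of an idealised hairpin)."""
    if name not in HAIRPIN_DEFINITIONS:
        raise ValueError(f"unknown hairpin template {name!r}")
    spec = HAIRPIN_DEFINITIONS[name]
    dih = np.tile(DIHEDRAL_LIBRARY["strand"], (n_res, 1))
    turn = spec["turn"]
    dih[turn[1] - first_id] = DIHEDRAL_LIBRARY["turn1"]
    dih[turn[2] - first_id] = DIHEDRAL_LIBRARY["turn2"]
    return dih


def hairpin_template(name: str, weight: float = 1.0,
                     cartesian_noise_nm: float = DEFAULT_CARTESIAN_NOISE_NM,
                     angular_noise_deg: float = 0.0) -> tuple[StateSpec, Conformation]:
    """(StateSpec, noise-free reference Conformation) for a hairpin state."""
    dih = hairpin_dihedrals(name)
    spec_def = HAIRPIN_DEFINITIONS[name]
    state = StateSpec(name, weight, dihedrals=dih,
                      angular_noise_deg=angular_noise_deg,
                      cartesian_noise_nm=cartesian_noise_nm,
                      metadata={"turn_residues": spec_def["turn"],
                                "strand_residues": spec_def["strands"]})
    phi = dih[:, 0].copy()
    psi = dih[:, 1].copy()
    phi[0] = np.nan
    psi[-1] = np.nan
    coords = build_backbone_batch(phi[None], psi[None])[0]
    atom_names, residue_ids, residue_names = default_topology()
    reference = Conformation(coords, atom_names, residue_ids, residue_names)
    reference.validate()
    return state, reference


# ---------------------------------------------------------------------------
# ensemble generation
# ---------------------------------------------------------------------------


def generate_ensemble(specs: Sequence[StateSpec], n_frames: int, temperature: float,
                      seed: int, dt_ps: float = 2.0) -> Ensemble:
    """Draw i.i.d. frames from a state mixture and build their coordinates.

    Per frame: the state is drawn from the mixture weights; dihedrals are the
    state library plus wrapped-Gaussian jitter (or fresh region-mixture draws
    for coil states); coordinates are built by natural extension and then
    jittered with isotropic Gaussian noise.  Identical seeds give
    byte-identical coordinates.
    """
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    validate_specs(specs)
    rng = np.random.default_rng(seed)
    n_res = seqmod.N_RESIDUES
    weights = np.array([s.weight for s in specs], dtype=float)
    labels = rng.choice(len(specs), size=n_frames, p=weights / weights.sum())

    phi = np.empty((n_frames, n_res))
    psi = np.empty((n_frames, n_res))
    for k, spec in enumerate(specs):
        idx = np.flatnonzero(labels == k)
        if not idx.size:
            continue
        if spec.dihedrals is not None:
            base = np.broadcast_to(spec.dihedrals, (idx.size, n_res, 2))
            jitter = rng.normal(0.0, spec.angular_noise_deg, size=(idx.size, n_res, 2)) \
                if spec.angular_noise_deg > 0 else 0.0
            draws = wrap_angle(base + jitter)
        else:
            draws = _region_mixture_draws(spec.region_weights, idx.size * n_res, rng)
            draws = draws.reshape(idx.size, n_res, 2)
        phi[idx] = draws[..., 0]
        psi[idx] = draws[..., 1]
    phi[:, 0] = np.nan
    psi[:, -1] = np.nan

    coords = build_backbone_batch(phi, psi)
    cart = np.array([s.cartesian_noise_nm for s in specs])[labels]
    noise_mask = cart > 0
    if noise_mask.any():
        coords = coords + rng.normal(0.0, 1.0, size=coords.shape) * cart[:, None, None]

    atom_names, residue_ids, residue_names = default_topology()
    return Ensemble(
        coords=coords,
        atom_names=atom_names,
        residue_ids=residue_ids,
        residue_names=residue_names,
        temperature=float(temperature),
        frame_times=dt_ps * np.arange(n_frames),
        provenance={
            "seed": int(seed),
            "states": [s.state for s in specs],
            "weights": weights.tolist(),
            "labels": labels,  # ground truth for recovery tests only
        },
    )


def table2_state_specs(weights: Mapping[str, float],
                       angular_noise_deg: float = DEFAULT_ANGULAR_NOISE_DEG,
                       cartesian_noise_nm: float = 0.002,
                       coil_region_weights: Mapping[str, float] | None = None
                       ) -> list[StateSpec]:
    """Whole-frame state mixture matched to the secondary-structure rule table.

    ``weights`` maps helix/ppii/strand/turn/coil to mixture probabilities
    (e.g. a column of the secondary-structure totals table).  The Cartesian
    jitter default is small because these states live in dihedral space:
    0.02 nm Cartesian noise on ~0.15 nm bonds would scramble the torsions.
    """
    kw = dict(angular_noise_deg=angular_noise_deg, cartesian_noise_nm=cartesian_noise_nm)
    specs = [
        uniform_state("helix", weights["helix"], **kw),
        uniform_state("ppii", weights["ppii"], **kw),
        uniform_state("strand", weights["strand"], **kw),
        turn_tiled_state(weights["turn"], **kw),
        coil_state(weights["coil"], coil_region_weights, **kw),
    ]
    validate_specs(specs)
    return specs


def spiked_hairpin_specs(name: str, fraction: float,
                         coil_region_weights: Mapping[str, float] | None = None,
                         cartesian_noise_nm: float = DEFAULT_CARTESIAN_NOISE_NM
                         ) -> tuple[list[StateSpec], Conformation]:
    """A hairpin state at ``fraction`` among heterogeneous coil frames."""
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    hp, reference = hairpin_template(name, weight=fraction,
                                     cartesian_noise_nm=cartesian_noise_nm)
    specs = [hp, coil_state(1.0 - fraction, coil_region_weights,
                            cartesian_noise_nm=cartesian_noise_nm)]
    return specs, reference


# ---------------------------------------------------------------------------
# temperature series
# ---------------------------------------------------------------------------


def temperature_series_spec(base: Sequence[StateSpec], ladder: Sequence[float],
                            trend: Mapping[str, float],
                            base_temperature: float = 278.0
                            ) -> dict[float, list[StateSpec]]:
    """Linearly temperature-dependent mixture weights, renormalised per rung.

    ``trend`` maps state name to a weight slope per kelvin.  At the base
    temperature the base spec is returned unchanged.  A weight leaving
    [0, 1] before renormalisation raises an error naming the temperature.
    """
    validate_specs(base)
    out: dict[float, list[StateSpec]] = {}
    for T in ladder:
        raw = []
        for spec in base:
            w = spec.weight + trend.get(spec.state, 0.0) * (T - base_temperature)
            if w < -1e-12 or w > 1.0 + 1e-12:
                raise ValueError(f"weight of state {spec.state!r} leaves [0, 1] at T={T} K")
            raw.append(min(max(w, 0.0), 1.0))
        total = sum(raw)
        out[float(T)] = [spec.with_weight(w / total) for spec, w in zip(base, raw)]
    return out
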