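"""File I/O: multi-model PDB ensembles, YAML state specs, CSV side-cars.

Multi-model PDB is the canonical interchange format; coordinates are stored
in angstroms on disk (PDB convention) and nanometres in memory.  Extra
atoms in an input file (side chains, termini) are ignored with a warning as
long as the 85-atom backbone topology can be extracted.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import yaml
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from . import sequence as seqmod
from .geometry import default_topology
from .synthetic import Ensemble, StateSpec, validate_specs

NM_PER_ANGSTROM = 0.1


def write_ensemble(ensemble: Ensemble, path) -> None:
    """Write an ensemble as a multi-model PDB file (one MODEL per frame)."""
    n_atoms = ensemble.coords.shape[1]
    atoms = struc.AtomArray(n_atoms)
    atoms.chain_id = np.full(n_atoms, "A")
    atoms.res_id = ensemble.residue_ids
    atoms.res_name = ensemble.residue_names
    atoms.atom_name = ensemble.atom_names
    atoms.element = np.array([name[0] for name in ensemble.atom_names])
    atoms.hetero = np.zeros(n_atoms, dtype=bool)
    stack = struc.from_template(atoms, ensemble.coords / NM_PER_ANGSTROM)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_ensemble(path, temperature: float = 300.0, dt_ps: float = 2.0) -> Ensemble:
    """Read a multi-model PDB into an Ensemble.

    Atoms that do not map onto the backbone topology (side chains etc.) are
    dropped with a warning; a residue missing any of N, H, CA, C, O is an
    error listing the offenders.
    """
    pdb = PDBFile.read(str(path))
    if pdb.get_model_count() == 0:
        raise ValueError(f"{path}: no models in file")
    stack = pdb.get_structure(model=None)
    atoms = stack[0]
    keep = np.isin(atoms.atom_name, list(seqmod.BACKBONE_ATOMS)) & np.isin(
        atoms.res_id, seqmod.RESIDUE_IDS
    )
    if keep.sum() < atoms.array_length():
        dropped = sorted(set(atoms.atom_name[~keep]))
        warnings.warn(f"{path}: ignoring non-backbone atoms {dropped}")

    # map (res_id, atom_name) -> canonical slot
    sub_res = atoms.res_id[keep]
    sub_name = atoms.atom_name[keep]
    order = np.full(seqmod.N_ATOMS, -1, dtype=int)
    kept_idx = np.flatnonzero(keep)
    for pos, (rid, name) in enumerate(zip(sub_res, sub_name)):
        slot = seqmod.atom_index(int(rid), str(name))
        if order[slot] != -1:
            raise ValueError(f"{path}: duplicate atom {name} in residue {rid}")
        order[slot] = kept_idx[pos]
    missing = np.flatnonzero(order == -1)
    if missing.size:
        names = [
            f"{seqmod.BACKBONE_ATOMS[m % 5]}@{seqmod.FIRST_RESIDUE_ID + m // 5}"
            for m in missing
        ]
        raise ValueError(f"{path}: atoms missing from topology: {names}")

    coords = stack.coord[:, order, :] * NM_PER_ANGSTROM
    atom_names, residue_ids, residue_names = default_topology()
    return Ensemble(
        coords=coords,
        atom_names=atom_names,
        residue_ids=residue_ids,
        residue_names=residue_names,
        temperature=float(temperature),
        frame_times=dt_ps * np.arange(coords.shape[0]),
        provenance={"source": str(path)},
    )


# ---------------------------------------------------------------------------
# state-spec YAML and label side-cars
# ---------------------------------------------------------------------------


def specs_to_yaml(specs, path) -> None:
    doc = []
    for s in specs:
        entry = {
            "state": s.state,
            "weight": float(s.weight),
            "angular_noise_deg": float(s.angular_noise_deg),
            "cartesian_noise_nm": float(s.cartesian_noise_nm),
        }
        if s.dihedrals is not None:
            entry["dihedrals"] = np.asarray(s.dihedrals).tolist()
        if s.region_weights is not None:
            entry["region_weights"] = {k: float(v) for k, v in s.region_weights.items()}
        if s.metadata:
            entry["metadata"] = s.metadata
        doc.append(entry)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def specs_from_yaml(path) -> list[StateSpec]:
    doc = yaml.safe_load(Path(path).read_text())
    specs = []
    for entry in doc:
        specs.append(
            StateSpec(
                state=entry["state"],
                weight=entry["weight"],
                dihedrals=np.array(entry["dihedrals"]) if "dihedrals" in entry else None,
                region_weights=entry.get("region_weights"),
                angular_noise_deg=entry.get("angular_noise_deg", 0.0),
                cartesian_noise_nm=entry.get("cartesian_noise_nm", 0.0),
                metadata=entry.get("metadata", {}),
            )
        )
    validate_specs(specs)
    return specs


def labels_to_csv(ensemble: Ensemble, path) -> None:
    """Ground-truth state labels as a CSV side-car (frame, state)."""
    labels = ensemble.provenance.get("labels")
    states = ensemble.provenance.get("states")
    if labels is None:
        raise ValueError("ensemble carries no generator labels")
    lines = ["frame,state"]
    for i, lab in enumerate(labels):
        lines.append(f"{i},{states[lab]}")
    Path(path).write_text("\n".join(lines) + "\n")
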