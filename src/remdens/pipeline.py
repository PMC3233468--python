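"""End-to-end analysis pipeline and its configuration.

`run_pipeline` executes, per temperature: Ramachandran region statistics
and PMF, secondary-structure propensities, the PC1/PC2 free-energy surface
with its minima, connectivity clustering with hairpin-template populations,
and the turn hydrogen-bond distance free-energy profile.  Outputs are CSV/
JSON tables laid out like the region-probability, secondary-structure and
FES-minima summary tables, plus a manifest recording seeds and rule
versions.  Outputs are written to a temporary directory and moved into
place only on success, so a failed stage leaves no partial results.
"""

from __future__ import annotations

import json
import shutil
import tempfile
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import (
    connectivity_cluster,
    distance_fe_profile,
    hairpin_population,
    hbond_distance_series,
    pairwise_rmsd,
    sasa_vs_distance,
)
from .fes import find_minima
from .io import read_ensemble
from .pca import pca_fes
from .rama import ramachandran_pmf, region_probabilities
from .secondary import RULE_VERSION, assign_ss, residue_propensities, total_propensities
from .synthetic import generate_ensemble, hairpin_template, spiked_hairpin_specs

#: hairpin populations per temperature used for the default synthetic inputs
DEFAULT_HAIRPIN_FRACTIONS = {278.0: 0.07, 298.0: 0.05, 320.0: 0.04}


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Settings of one pipeline run; free-text model label is metadata only."""

    model_label: str = "synthetic"
    temperatures: tuple = (278.0, 298.0, 320.0)
    n_frames: int = 2000
    seed: int = 0
    cluster_cutoff_nm: float = 0.15
    cluster_stride: int = 1
    rama_bin_deg: float = 10.0
    pc_bin_nm: float = 0.1
    distance_bin_nm: float = 0.05
    n_blocks: int = 4
    hairpin: str = "hairpin1"
    sasa_frames: int = 0  # frames for the SASA stage; 0 skips it
    inputs: dict = field(default_factory=dict)  # temperature -> PDB path
    out_dir: str = "remdens_out"

    def validate(self) -> None:
        if self.n_frames <= 0 or self.cluster_stride < 1 or self.n_blocks < 2:
            raise ValueError("numeric settings must be positive")
        for T, path in self.inputs.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"input for {T} K not found: {path}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if "temperatures" in doc:
            doc["temperatures"] = tuple(doc["temperatures"])
        return cls(**doc)


def _load_or_generate(config: RunConfig, temperature: float):
    if temperature in config.inputs:
        return read_ensemble(config.inputs[temperature], temperature=temperature)
    fraction = DEFAULT_HAIRPIN_FRACTIONS.get(temperature, 0.05)
    specs, _ = spiked_hairpin_specs(config.hairpin, fraction)
    # per-temperature sub-seed keeps runs independent yet reproducible
    seed = int(config.seed * 1000 + round(temperature)) % (2**31)
    return generate_ensemble(specs, config.n_frames, temperature, seed=seed)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage for every configured temperature.

    Returns a dict with the output directory and per-temperature summaries;
    writes table-layout CSVs, cluster reports, profiles and a manifest.
    """
    config.validate()
    _, template = hairpin_template(config.hairpin)
    out_final = Path(config.out_dir)
    tmp = Path(tempfile.mkdtemp(prefix="remdens_"))
    summary: dict = {"temperatures": {}}

    region_tbl: dict[str, dict] = {}
    ss_tbl: dict[str, dict] = {}
    minima_rows = []
    try:
        for T in config.temperatures:
            col = f"{config.model_label} T={T:g} K"
            try:
                ens = _load_or_generate(config, T)
            except Exception as e:  # noqa: BLE001
                raise PipelineStageError("input", e)

            try:
                table = ens.dihedral_table()
                rp = region_probabilities(table)
                region_tbl[col] = rp.as_dict()
                grid = ramachandran_pmf(table, T, config.rama_bin_deg)
                np.savetxt(tmp / f"rama_pmf_{T:g}K.csv",
                           np.where(np.isnan(grid.free_energy), np.inf, grid.free_energy),
                           delimiter=",")
            except PipelineStageError:
                raise
            except Exception as e:  # noqa: BLE001
                raise PipelineStageError("rama", e)

            try:
                ss = assign_ss(table)
                ss_tbl[col] = total_propensities(ss)
                per_res = residue_propensities(ss)
                pd.DataFrame(per_res, index=table.residue_ids).rename_axis("residue") \
                    .to_csv(tmp / f"ss_residue_{T:g}K.csv")
            except Exception as e:  # noqa: BLE001
                raise PipelineStageError("secondary_structure", e)

            try:
                grid2, _model = pca_fes(ens, temperature=T, bin_nm=config.pc_bin_nm)
                # keep the noise floor meaningful for small ensembles
                floor = max(1, min(5, ens.n_frames // 10))
                minima = find_minima(grid2, occupancy_floor=floor)
                for pc1, pc2, depth in minima.minima:
                    minima_rows.append(
                        {"model": config.model_label, "T_K": T,
                         "pc1_nm": pc1, "pc2_nm": pc2, "depth_kj_mol": depth})
            except Exception as e:  # noqa: BLE001
                raise PipelineStageError("pca_fes", e)

            try:
                matrix, idx = pairwise_rmsd(ens, stride=config.cluster_stride)
                clusters = connectivity_cluster(matrix, config.cluster_cutoff_nm, idx)
                pop = hairpin_population(clusters, ens, template)
                is_rep = np.zeros(len(clusters.labels), dtype=bool)
                is_rep[clusters.representatives] = True
                pd.DataFrame({"frame": idx, "cluster": clusters.labels,
                              "is_representative": is_rep}) \
                    .to_csv(tmp / f"clusters_{T:g}K.csv", index=False)
            except Exception as e:  # noqa: BLE001
                raise PipelineStageError("clustering", e)

            try:
                dist = hbond_distance_series(ens, config.hairpin)
                prof = distance_fe_profile(dist, T, config.distance_bin_nm, config.n_blocks)
                pd.DataFrame({"distance_nm": prof.bin_centers,
                              "delta_f_kj_mol": prof.delta_f,
                              "block_sd_kj_mol": prof.block_sd}) \
                    .to_csv(tmp / f"hbond_profile_{T:g}K.csv", index=False)
            except Exception as e:  # noqa: BLE001
                raise PipelineStageError("distance_profile", e)

            if config.sasa_frames > 0:
                try:
                    sub = np.linspace(0, ens.n_frames - 1, config.sasa_frames).astype(int)
                    sp = sasa_vs_distance(ens, dist, config.distance_bin_nm,
                                          config.n_blocks, frames=sub)
                    pd.DataFrame({"distance_nm": sp.bin_centers,
                                  "s_lvffa_nm2": sp.s_lvffa, "s_lvffa_sd": sp.s_lvffa_sd,
                                  "f_lvffa": sp.f_lvffa, "f_lvffa_sd": sp.f_lvffa_sd}) \
                        .to_csv(tmp / f"sasa_profile_{T:g}K.csv", index=False)
                except Exception as e:  # noqa: BLE001
                    raise PipelineStageError("sasa", e)

            summary["temperatures"][T] = {
                "regions": region_tbl[col],
                "ss_totals": ss_tbl[col],
                "hairpin_population": pop,
                "n_clusters": clusters.n_clusters,
            }

        pd.DataFrame(region_tbl).rename_axis("region").to_csv(tmp / "table_regions.csv")
        pd.DataFrame(ss_tbl).rename_axis("structure").to_csv(tmp / "table_ss_totals.csv")
        pd.DataFrame(minima_rows).to_csv(tmp / "table_fes_minima.csv", index=False)
        manifest = {
            "package_version": __version__,
            "ss_rule_version": RULE_VERSION,
            "pca_superposition": "iterative-mean-ca-fit-2-rounds",
            "fe_reference": "lowest-populated-bin-zero",
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(config).items()},
        }
        (tmp / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except Exception:
        shutil.rmtree(tmp, ignore_errors=True)
        raise

    if out_final.exists():
        shutil.rmtree(out_final)
    shutil.move(str(tmp), str(out_final))
    summary["out_dir"] = str(out_final)
    return summary
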