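"""Connectivity clustering on C-alpha RMSD and beta-hairpin analyses.

Frames are clustered as the connected components of the graph whose edges
join conformations with pairwise C-alpha RMSD below a cutoff (0.15 nm by
default): members of a cluster need only be *chained* below the cutoff, not
mutually close.  Cluster representatives are medoids (minimum mean
intra-cluster RMSD).  On top of the clustering the module measures hairpin
template populations, RMSD-to-template series, turn hydrogen-bond distance
free-energy profiles (Boltzmann inversion with block-averaged errors) and
hydrophobic solvent exposure versus that distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator, ClusterMixin

from .fes import R_GAS
from .geometry import (
    Conformation,
    pairwise_rmsd_matrix,
    rmsd_to_reference,
    shrake_rupley_sasa,
)
from .sequence import LVFFA_RESIDUES
from .synthetic import Ensemble

DEFAULT_CUTOFF_NM = 0.15

#: named turn hydrogen-bond atom pairs (donor H, acceptor O)
HBOND_PAIRS = {
    "hairpin1": ((22, "H"), (19, "O")),
    "hairpin2": ((20, "H"), (17, "O")),
}


@dataclass
class ClusterSet:
    """Frame -> cluster labels with populations and medoid representatives."""

    labels: np.ndarray  # (n_frames,) cluster id, 0-based, descending size
    populations: np.ndarray  # fraction per cluster, sums to 1
    representatives: np.ndarray  # frame index per cluster (medoid)
    cutoff: float
    frame_indices: np.ndarray = None  # type: ignore[assignment]  # into the source ensemble

    def __post_init__(self):
        if self.frame_indices is None:
            self.frame_indices = np.arange(len(self.labels))

    @property
    def n_clusters(self) -> int:
        return len(self.populations)

    def validate(self) -> None:
        if not np.isclose(self.populations.sum(), 1.0):
            raise ValueError("cluster populations must sum to 1")
        for cid, rep in enumerate(self.representatives):
            if self.labels[rep] != cid:
                raise ValueError("representative must belong to its cluster")


class ConnectivityClustering(BaseEstimator, ClusterMixin):
    """Single-linkage-at-cutoff clustering on a precomputed RMSD matrix.

    Parameters
    ----------
    cutoff:
        Edge threshold in nm; frames closer than this are connected.

    Attributes (after ``fit``)
    --------------------------
    labels_ : cluster id per frame (0-based, ordered by descending size)
    populations_ : fraction of frames per cluster
    medoids_ : frame index of each cluster's medoid representative
    """

    def __init__(self, cutoff: float = DEFAULT_CUTOFF_NM):
        self.cutoff = cutoff

    def fit(self, X, y=None):
        D = np.asarray(X, dtype=float)
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("expected a square pairwise distance matrix")
        n = D.shape[0]
        adj = csr_matrix(D < self.cutoff)
        n_comp, raw = connected_components(adj, directed=False)
        sizes = np.bincount(raw, minlength=n_comp)
        # stable relabel by descending size (ties by first occurrence)
        order = np.lexsort((np.arange(n_comp), -sizes))
        relabel = np.empty(n_comp, dtype=int)
        relabel[order] = np.arange(n_comp)
        labels = relabel[raw]
        medoids = np.empty(n_comp, dtype=int)
        for cid in range(n_comp):
            members = np.flatnonzero(labels == cid)
            sub = D[np.ix_(members, members)]
            medoids[cid] = members[np.argmin(sub.mean(axis=1))]
        self.labels_ = labels
        self.populations_ = np.bincount(labels, minlength=n_comp) / n
        self.medoids_ = medoids
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def pairwise_rmsd(ensemble: Ensemble, stride: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric C-alpha RMSD matrix over strided frames.

    Returns ``(matrix, frame_indices)`` where ``frame_indices`` maps matrix
    rows back to ensemble frames.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    idx = np.arange(0, ensemble.n_frames, stride)
    return pairwise_rmsd_matrix(ensemble.ca_stack()[idx]), idx


def connectivity_cluster(matrix: np.ndarray, cutoff: float = DEFAULT_CUTOFF_NM,
                         frame_indices=None) -> ClusterSet:
    """Connected-component clustering of a pairwise RMSD matrix."""
    est = ConnectivityClustering(cutoff=cutoff).fit(matrix)
    cs = ClusterSet(est.labels_, est.populations_, est.medoids_, cutoff,
                    None if frame_indices is None else np.asarray(frame_indices))
    cs.validate()
    return cs


def hairpin_population(clusters: ClusterSet, ensemble: Ensemble,
                       template: Conformation) -> float:
    """Population of the cluster whose medoid is nearest the template.

    Returns 0 when no cluster representative lies within the clustering
    cutoff of the template reference.
    """
    ca = ensemble.ca_stack()[clusters.frame_indices[clusters.representatives]]
    d = rmsd_to_reference(ca, template.ca_coords())
    best = int(np.argmin(d))
    if d[best] >= clusters.cutoff:
        return 0.0
    return float(clusters.populations[best])


def rmsd_to_template_series(ensembles, template: Conformation):
    """Per-frame C-alpha RMSD (nm) to a template reference.

    ``ensembles`` may be one Ensemble or a mapping temperature -> Ensemble;
    the return mirrors the input shape.
    """
    ref = template.ca_coords()
    if isinstance(ensembles, Ensemble):
        return rmsd_to_reference(ensembles.ca_stack(), ref)
    return {T: rmsd_to_reference(e.ca_stack(), ref) for T, e in ensembles.items()}


def hbond_distance_series(ensemble: Ensemble, pair) -> np.ndarray:
    """Euclidean donor-H to acceptor-O distance per frame, nm.

    ``pair`` is a name from HBOND_PAIRS ("hairpin1" = E22(H)-F19(O),
    "hairpin2" = F20(H)-L17(O)) or an explicit ((res, atom), (res, atom))
    tuple.
    """
    if isinstance(pair, str):
        if pair not in HBOND_PAIRS:
            raise ValueError(f"unknown hydrogen-bond pair {pair!r}")
        pair = HBOND_PAIRS[pair]
    (r1, a1), (r2, a2) = pair
    x1 = ensemble.atom_series(r1, a1)
    x2 = ensemble.atom_series(r2, a2)
    return np.linalg.norm(x1 - x2, axis=1)


# ---------------------------------------------------------------------------
# profiles along the hydrogen-bond distance
# ---------------------------------------------------------------------------


@dataclass
class FreeEnergyProfile:
    """Delta F versus distance with block-averaged standard deviations."""

    bin_centers: np.ndarray  # nm
    delta_f: np.ndarray  # kJ/mol, NaN where unpopulated
    block_sd: np.ndarray  # kJ/mol, NaN where undefined
    temperature: float
    reference_bin: int  # index of the zero (global-minimum) bin

    def validate(self) -> None:
        if not np.isclose(self.delta_f[self.reference_bin], 0.0):
            raise ValueError("delta F must be zero at the reference bin")
        sd = self.block_sd[np.isfinite(self.block_sd)]
        if np.any(sd < 0):
            raise ValueError("block errors must be non-negative")


@dataclass
class SASAProfile:
    """Hydrophobic SASA and its fraction of total SASA versus distance."""

    bin_centers: np.ndarray  # nm
    s_lvffa: np.ndarray  # nm^2, mean per bin (NaN where empty)
    s_lvffa_sd: np.ndarray
    f_lvffa: np.ndarray  # fraction of total SASA
    f_lvffa_sd: np.ndarray


def _nan_sd(per_block: np.ndarray) -> np.ndarray:
    """Column SD over blocks, NaN where fewer than 2 blocks are populated."""
    n_ok = np.sum(np.isfinite(per_block), axis=0)
    out = np.full(per_block.shape[1], np.nan)
    ok = n_ok >= 2
    if ok.any():
        out[ok] = np.nanstd(per_block[:, ok], axis=0, ddof=1)
    return out


def _block_slices(n: int, n_blocks: int):
    edges = np.linspace(0, n, n_blocks + 1).astype(int)
    return [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]


def distance_fe_profile(series: np.ndarray, temperature: float, bin_nm: float = 0.05,
                        n_blocks: int = 4) -> FreeEnergyProfile:
    """Boltzmann-inverted free-energy profile along a distance series.

    Delta F(bin) = -RT ln(P(bin) / P(reference)) with the reference taken as
    the most populated bin, so the profile is >= 0 with its minimum at zero
    (the same convention as the 2-D surfaces).  Errors are standard
    deviations over ``n_blocks`` equal contiguous blocks, evaluated against
    the full-series reference bin.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty distance series")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    lo = np.floor(series.min() / bin_nm) * bin_nm
    hi = np.ceil(series.max() / bin_nm) * bin_nm
    n_bins = max(int(round((hi - lo) / bin_nm)), 1)
    edges = lo + bin_nm * np.arange(n_bins + 1)
    counts, _ = np.histogram(series, bins=edges)
    ref = int(np.argmax(counts))
    with np.errstate(divide="ignore"):
        delta_f = -R_GAS * temperature * np.log(counts / counts[ref])
    delta_f[counts == 0] = np.nan

    block_vals = np.full((n_blocks, n_bins), np.nan)
    for b, sl in enumerate(_block_slices(series.size, n_blocks)):
        c, _ = np.histogram(series[sl], bins=edges)
        if c[ref] > 0:
            with np.errstate(divide="ignore"):
                f = -R_GAS * temperature * np.log(c / c[ref])
            f[c == 0] = np.nan
            block_vals[b] = f
    block_sd = _nan_sd(block_vals)

    profile = FreeEnergyProfile(0.5 * (edges[:-1] + edges[1:]), delta_f, block_sd,
                                temperature, ref)
    profile.validate()
    return profile


def lvffa_sasa(ensemble: Ensemble, frames=None, n_points: int = 256
               ) -> tuple[np.ndarray, np.ndarray]:
    """(S_LVFFA, f_LVFFA) per frame: backbone SASA of residues L17-A21 and
    its fraction of the total backbone SASA."""
    idx = np.arange(ensemble.n_frames) if frames is None else np.asarray(frames)
    lv_mask = np.isin(ensemble.residue_ids, LVFFA_RESIDUES)
    s = np.empty(idx.size)
    f = np.empty(idx.size)
    for k, i in enumerate(idx):
        per_atom = shrake_rupley_sasa(ensemble.frame(int(i)), n_points=n_points)
        total = per_atom.sum()
        s[k] = per_atom[lv_mask].sum()
        f[k] = s[k] / total
    return s, f


def sasa_vs_distance(ensemble: Ensemble, series: np.ndarray, bin_nm: float = 0.05,
                     n_blocks: int = 4, frames=None, n_points: int = 256) -> SASAProfile:
    """Hydrophobic solvent exposure binned along the H-bond distance.

    Empty bins are reported as NaN (missing), never zero; block standard
    deviations need at least two populated blocks and are NaN otherwise.
    """
    series = np.asarray(series, dtype=float)
    idx = np.arange(ensemble.n_frames) if frames is None else np.asarray(frames)
    d = series[idx]
    s, f = lvffa_sasa(ensemble, frames=idx, n_points=n_points)

    lo = np.floor(d.min() / bin_nm) * bin_nm
    hi = np.ceil(d.max() / bin_nm) * bin_nm
    n_bins = max(int(round((hi - lo) / bin_nm)), 1)
    edges = lo + bin_nm * np.arange(n_bins + 1)
    which = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)

    def _bin_mean(values):
        out = np.full(n_bins, np.nan)
        for b in range(n_bins):
            sel = which == b
            if sel.any():
                out[b] = values[sel].mean()
        return out

    block_ids = np.empty(idx.size, dtype=int)
    for b, sl in enumerate(_block_slices(idx.size, n_blocks)):
        block_ids[sl] = b

    def _block_sd(values):
        per_block = np.full((n_blocks, n_bins), np.nan)
        for blk in range(n_blocks):
            for b in range(n_bins):
                sel = (block_ids == blk) & (which == b)
                if sel.any():
                    per_block[blk, b] = values[sel].mean()
        return _nan_sd(per_block)

    return SASAProfile(0.5 * (edges[:-1] + edges[1:]),
                       _bin_mean(s), _block_sd(s), _bin_mean(f), _block_sd(f))
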