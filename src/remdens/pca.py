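"""Backbone principal-component analysis and PC-plane free-energy surfaces.

The PCA operates on the 51 heavy backbone atoms N, CA, C of the 17 residues
(3 x 51 = 153 coordinates); the amide H and carbonyl O are excluded, which
is the only atom set consistent with a 51-atom backbone for this peptide.
Frames are iteratively superposed (C-alpha fit) onto the running mean
structure before the covariance is accumulated, so the modes describe
internal fluctuations, not rigid-body motion.  Eigenvector signs are made
deterministic by forcing the largest-magnitude component positive.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .fes import FESGrid, FESMinima, fes_2d, find_minima
from .geometry import kabsch_superpose
from .sequence import ATOMS_PER_RESIDUE

#: indices of N, CA, C inside one 5-atom residue block
_PCA_ATOM_OFFSETS = (0, 2, 3)
#: index of CA within the (N, CA, C) triplet
_CA_WITHIN_TRIPLET = 1


def backbone_nca_stack(ensemble) -> np.ndarray:
    """(n_frames, 51, 3) N/CA/C coordinates from an Ensemble or coords stack."""
    coords = ensemble.coords if hasattr(ensemble, "coords") else np.asarray(ensemble, float)
    n_res = coords.shape[-2] // ATOMS_PER_RESIDUE
    idx = (np.arange(n_res)[:, None] * ATOMS_PER_RESIDUE
           + np.array(_PCA_ATOM_OFFSETS)[None, :]).ravel()
    return coords[..., idx, :]


def _superpose_stack(stack: np.ndarray, reference: np.ndarray, fit_idx: np.ndarray
                     ) -> np.ndarray:
    """Rigid-fit every frame onto ``reference`` using the ``fit_idx`` atoms."""
    out = np.empty_like(stack)
    ref_sel = reference[fit_idx]
    for i, frame in enumerate(stack):
        R, t, _ = kabsch_superpose(frame[fit_idx], ref_sel)
        out[i] = frame @ R.T + t
    return out


class BackbonePCA(BaseEstimator, TransformerMixin):
    """Principal components of backbone-atom fluctuations.

    Parameters
    ----------
    n_superpose_rounds:
        Rounds of the iterative mean-structure fit (fit all frames onto the
        running mean, recompute the mean) before the covariance is formed.
    fit_atoms:
        Atom subset used for the rigid fit; "ca" (default) or "all".

    Attributes (after ``fit``)
    --------------------------
    mean_ : (51, 3) mean structure, nm
    components_ : (n_modes, 153) orthonormal eigenvectors, descending variance
    explained_variance_ : eigenvalues, nm^2
    """

    def __init__(self, n_superpose_rounds: int = 2, fit_atoms: str = "ca"):
        self.n_superpose_rounds = n_superpose_rounds
        self.fit_atoms = fit_atoms

    def _fit_indices(self, n_atoms: int) -> np.ndarray:
        if self.fit_atoms == "all":
            return np.arange(n_atoms)
        if self.fit_atoms == "ca":
            return np.arange(n_atoms // 3) * 3 + _CA_WITHIN_TRIPLET
        raise ValueError("fit_atoms must be 'ca' or 'all'")

    def fit(self, X, y=None):
        """Fit on stacked N/CA/C coordinates, shape (n_frames, 51, 3) or (n_frames, 153)."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X.reshape(X.shape[0], -1, 3)
        if X.shape[0] < 2:
            raise ValueError("PCA needs at least 2 frames")
        n_frames, n_atoms, _ = X.shape
        fit_idx = self._fit_indices(n_atoms)

        aligned = _superpose_stack(X, X[0], fit_idx)
        mean = aligned.mean(axis=0)
        for _ in range(self.n_superpose_rounds):
            aligned = _superpose_stack(X, mean, fit_idx)
            mean = aligned.mean(axis=0)
        # final pass against the stored mean so transform() reproduces the
        # exact alignment used for the covariance
        aligned = _superpose_stack(X, mean, fit_idx)
        sample_mean = aligned.mean(axis=0)

        flat = aligned.reshape(n_frames, -1)
        centred = flat - sample_mean.ravel()
        cov = centred.T @ centred / n_frames
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0.0, None)
        evecs = evecs[:, order].T  # rows are modes
        # deterministic sign: largest-magnitude component positive
        for v in evecs:
            if v[np.argmax(np.abs(v))] < 0:
                v *= -1.0

        self.n_atoms_ = n_atoms
        self.fit_idx_ = fit_idx
        self.mean_ = mean
        self.components_ = evecs
        self.explained_variance_ = evals
        return self

    def transform(self, X) -> np.ndarray:
        """Project frames onto all modes; column k is PC(k+1), nm."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X.reshape(X.shape[0], -1, 3)
        if X.shape[1] != self.n_atoms_:
            raise ValueError("topology does not match the fitted model")
        aligned = _superpose_stack(X, self.mean_, self.fit_idx_)
        centred = aligned.reshape(X.shape[0], -1) - self.mean_.ravel()
        return centred @ self.components_.T

    def inverse_transform(self, projections: np.ndarray) -> np.ndarray:
        """Back-project mode amplitudes to superposed coordinates (n, 51, 3)."""
        flat = self.mean_.ravel() + np.asarray(projections, float) @ self.components_
        return flat.reshape(-1, self.n_atoms_, 3)


# ---------------------------------------------------------------------------
# module-level wrappers (spec surface)
# ---------------------------------------------------------------------------


def fit_pca(ensemble, n_superpose_rounds: int = 2) -> BackbonePCA:
    """Fit a BackbonePCA model on an ensemble's N/CA/C atoms."""
    return BackbonePCA(n_superpose_rounds=n_superpose_rounds).fit(backbone_nca_stack(ensemble))


def project(ensemble, model: BackbonePCA, n_modes: int = 2) -> np.ndarray:
    """(PC1..PCn) series in nm for every frame of an ensemble."""
    return model.transform(backbone_nca_stack(ensemble))[:, :n_modes]


def pca_fes(ensemble, temperature: float | None = None, bin_nm: float = 0.1,
            model: BackbonePCA | None = None) -> tuple[FESGrid, BackbonePCA]:
    """Free-energy surface on (PC1, PC2) for one ensemble."""
    model = model or fit_pca(ensemble)
    pcs = project(ensemble, model)
    T = temperature if temperature is not None else ensemble.temperature
    return fes_2d(pcs[:, 0], pcs[:, 1], T, bin_nm), model


def fes_minima(grid: FESGrid, occupancy_floor: int = 5) -> FESMinima:
    """Local minima with depths relative to the global minimum (re-export)."""
    return find_minima(grid, occupancy_floor=occupancy_floor)
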