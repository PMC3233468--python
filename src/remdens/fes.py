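"""Boltzmann-inversion free-energy grids shared by the Ramachandran and PCA stages.

A free-energy surface here is always a histogram inverted as
``F = -RT ln(P / P_max)`` so that the most populated bin sits at zero;
empty bins carry no free-energy value and are masked.  R is the gas
constant in kJ mol^-1 K^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

R_GAS = 8.314e-3  # kJ mol^-1 K^-1


@dataclass
class FESGrid:
    """Binned 2-D free energy (kJ/mol) with occupancy counts and an empty-bin mask."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    free_energy: np.ndarray  # (nx, ny), NaN where masked
    counts: np.ndarray  # (nx, ny) raw occupancy
    temperature: float  # K
    reference: str = "lowest-populated-bin-zero"

    @property
    def mask(self) -> np.ndarray:
        """True where a bin is empty (no free-energy value)."""
        return self.counts == 0

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    def validate(self) -> None:
        populated = self.free_energy[~self.mask]
        if populated.size and not np.isclose(populated.min(), 0.0):
            raise ValueError("populated minimum of a free-energy grid must be zero")
        if not np.all(np.isnan(self.free_energy[self.mask])):
            raise ValueError("masked bins must carry no free-energy value")


@dataclass
class FESMinima:
    """Local minima of a free-energy surface with depths relative to the global one."""

    minima: list  # of (x, y, depth kJ/mol), depth 0 for the global minimum

    def __post_init__(self):
        depths = [m[2] for m in self.minima]
        if depths and (min(depths) != 0.0 or any(d < 0 for d in depths)):
            raise ValueError("depths must be >= 0 with exactly one zero")


def free_energy_from_counts(counts: np.ndarray, temperature: float) -> np.ndarray:
    """-RT ln(P/P_max) per bin; empty bins NaN.  Invariant under count scaling."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    counts = np.asarray(counts, dtype=float)
    if counts.max() <= 0:
        raise ValueError("histogram is empty")
    with np.errstate(divide="ignore"):
        f = -R_GAS * temperature * np.log(counts / counts.max())
    f[counts == 0] = np.nan
    return f


def grid_edges(values: np.ndarray, bin_width: float) -> np.ndarray:
    """Bin edges at integer multiples of ``bin_width`` covering the data.

    Centers therefore fall on half-integer multiples (0.1 nm bins give
    centers like 2.05 or -0.25)."""
    lo = np.floor(values.min() / bin_width) * bin_width
    hi = np.ceil(values.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    n = int(round((hi - lo) / bin_width))
    return lo + bin_width * np.arange(n + 1)


def fes_2d(x: np.ndarray, y: np.ndarray, temperature: float, bin_width: float) -> FESGrid:
    """Two-dimensional Boltzmann-inverted histogram on (x, y)."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xe = grid_edges(x, bin_width)
    ye = grid_edges(y, bin_width)
    counts, _, _ = np.histogram2d(x, y, bins=(xe, ye))
    grid = FESGrid(xe, ye, free_energy_from_counts(counts, temperature), counts, temperature)
    grid.validate()
    return grid


def find_minima(grid: FESGrid, occupancy_floor: int = 5, merge_radius: int = 2) -> FESMinima:
    """Local minima of the surface over the 8-neighbourhood.

    Only bins with occupancy >= ``occupancy_floor`` are candidates; minima
    within ``merge_radius`` bins (Chebyshev) of a deeper one are merged into
    it.  Depths are relative to the global populated minimum (zero).
    """
    F = grid.free_energy
    counts = grid.counts
    if not np.any(counts > 0):
        raise ValueError("empty free-energy grid")
    padded = np.full((F.shape[0] + 2, F.shape[1] + 2), np.inf)
    work = np.where(np.isnan(F), np.inf, F)
    padded[1:-1, 1:-1] = work
    is_min = np.ones_like(work, dtype=bool)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == dj == 0:
                continue
            nb = padded[1 + di:padded.shape[0] - 1 + di, 1 + dj:padded.shape[1] - 1 + dj]
            is_min &= work <= nb
    is_min &= counts >= occupancy_floor
    cand = sorted(
        ((work[i, j], i, j) for i, j in zip(*np.nonzero(is_min))),
    )
    kept: list[tuple[float, int, int]] = []
    for f, i, j in cand:
        if all(max(abs(i - ki), abs(j - kj)) > merge_radius for _, ki, kj in kept):
            kept.append((f, i, j))
    if not kept:
        raise ValueError("no minima above the occupancy floor")
    f0 = kept[0][0]
    xc, yc = grid.x_centers, grid.y_centers
    return FESMinima([(float(xc[i]), float(yc[j]), float(f - f0)) for f, i, j in kept])
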