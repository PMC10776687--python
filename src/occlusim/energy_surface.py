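"""Gridded 2-D free-energy surfaces shared by the synthetic oracle and the MSM chain."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class FreeEnergySurface:
    """Free energies on a 2-D bin grid.

    ``g`` is in kJ/mol, shifted so the minimum over occupied bins is 0.
    ``mask`` is True on empty (unoccupied) bins; ``g`` is NaN there.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    g: np.ndarray
    mask: np.ndarray
    kt: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x_edges = np.asarray(self.x_edges, dtype=float)
        self.y_edges = np.asarray(self.y_edges, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        nx, ny = len(self.x_edges) - 1, len(self.y_edges) - 1
        if self.g.shape != (nx, ny) or self.mask.shape != (nx, ny):
            raise ValueError(f"grid shape mismatch: g {self.g.shape} vs bins ({nx},{ny})")
        occ = self.g[~self.mask]
        if occ.size and not np.isfinite(occ).all():
            raise ValueError("non-finite free energy on occupied bins")

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    def occupied_values(self) -> np.ndarray:
        return self.g[~self.mask]


def from_bin_weights(weights: np.ndarray, x_edges, y_edges, kt: float,
                     meta: dict | None = None) -> FreeEnergySurface:
    """Boltzmann-invert per-bin probability weights: G = -kT ln w, min-shifted."""
    weights = np.asarray(weights, dtype=float)
    mask = weights <= 0
    g = np.full(weights.shape, np.nan)
    with np.errstate(divide="ignore"):
        g[~mask] = -kt * np.log(weights[~mask])
    if (~mask).any():
        g[~mask] -= np.nanmin(g[~mask])
    return FreeEnergySurface(x_edges, y_edges, g, mask, kt, meta or {})


def make_grid(x_range, y_range, bins=50, pad_fraction=0.0):
    """Uniform bin edges over padded ranges; ``bins`` is int or (nx, ny)."""
    nx, ny = (bins, bins) if np.isscalar(bins) else bins
    (x0, x1), (y0, y1) = x_range, y_range
    px, py = pad_fraction * (x1 - x0), pad_fraction * (y1 - y0)
    return (np.linspace(x0 - px, x1 + px, nx + 1),
            np.linspace(y0 - py, y1 + py, ny + 1))
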