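"""Niche-overlap indices between two habitat-suitability surfaces.

Schoener's D and Hellinger-based I compare two suitability grids after
normalising each to a probability distribution over valid cells. Both
lie in [0, 1]: 0 means disjoint niches, 1 identical ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SuitabilityGrid",
    "schoeners_d",
    "hellingers_i",
    "read_grid",
    "write_grid",
]


@dataclass
class SuitabilityGrid:
    """A gridded suitability surface with values in [0, 1].

    ``values`` may contain NaN for no-data cells; two grids being
    compared must agree in shape *and* no-data mask.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        finite = np.isfinite(self.values)
        if finite.any() and (
            (self.values[finite] < 0).any() or (self.values[finite] > 1).any()
        ):
            raise ValueError("suitability values must lie in [0, 1]")

    @property
    def mask(self) -> np.ndarray:
        """Boolean array of valid (data) cells."""
        return np.isfinite(self.values)


def _normalised_pair(a: SuitabilityGrid, b: SuitabilityGrid):
    if a.values.shape != b.values.shape:
        raise ValueError("grids must share a shape")
    if not np.array_equal(a.mask, b.mask):
        raise ValueError("grids must share the same no-data mask")
    pa = a.values[a.mask]
    pb = b.values[b.mask]
    sa, sb = pa.sum(), pb.sum()
    if sa <= 0 or sb <= 0:
        raise ValueError("overlap undefined: a grid has zero total suitability")
    return pa / sa, pb / sb


def schoeners_d(a: SuitabilityGrid, b: SuitabilityGrid) -> float:
    """Schoener's D = 1 - 0.5 * sum |p_a - p_b| over valid cells."""
    pa, pb = _normalised_pair(a, b)
    return float(1.0 - 0.5 * np.abs(pa - pb).sum())


def hellingers_i(a: SuitabilityGrid, b: SuitabilityGrid) -> float:
    """Hellinger-based overlap I = 1 - 0.5 * sum (sqrt(p_a) - sqrt(p_b))^2."""
    pa, pb = _normalised_pair(a, b)
    return float(1.0 - 0.5 * ((np.sqrt(pa) - np.sqrt(pb)) ** 2).sum())


def read_grid(path, no_data: float = -1.0) -> SuitabilityGrid:
    """Read a plain-text matrix; cells equal to ``no_data`` become NaN."""
    vals = np.loadtxt(path, ndmin=2)
    vals = np.where(vals == no_data, np.nan, vals)
    return SuitabilityGrid(values=vals)


def write_grid(grid: SuitabilityGrid, path, no_data: float = -1.0) -> None:
    out = np.where(np.isfinite(grid.values), grid.values, no_data)
    np.savetxt(path, out, fmt="%.6g")
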