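"""Piecewise-linear HU to physical-density conversion.

A generic lookup table maps CT numbers to mass density rho (g/cm^3);
density doubles as the relative proton stopping power in this package's
simplified beam model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

#: Default table nodes (HU, g/cm^3); linear between nodes, clamped outside.
DEFAULT_NODES: Tuple[Tuple[float, float], ...] = (
    (-1000.0, 0.001),
    (-100.0, 0.93),
    (0.0, 1.0),
    (100.0, 1.09),
    (1000.0, 1.6),
)


@dataclass
class HuDensityTable:
    """Monotone piecewise-linear map HU -> density.

    Invariants: nodes sorted by HU, densities non-decreasing,
    rho(-1000) ~ air, rho(0) = 1 (water).
    """

    nodes: Tuple[Tuple[float, float], ...] = DEFAULT_NODES

    def __post_init__(self) -> None:
        nodes = tuple((float(h), float(r)) for h, r in self.nodes)
        hu = np.array([n[0] for n in nodes])
        rho = np.array([n[1] for n in nodes])
        if np.any(np.diff(hu) <= 0):
            raise ValueError("HU nodes must be strictly increasing")
        if np.any(np.diff(rho) < 0):
            raise ValueError("density must be non-decreasing in HU")
        self.nodes = nodes
        self._hu = hu
        self._rho = rho

    def density(self, hu: np.ndarray) -> np.ndarray:
        """Density (g/cm^3) for an array of HU values (clamped at ends)."""
        return np.interp(np.asarray(hu, dtype=float), self._hu, self._rho)

    __call__ = density
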