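"""Factor spaces, level grids and box regions for fermentation experiments.

A *factor* is a controllable bioreactor setting (pH, agitation speed,
aeration rate).  Uniform designs place runs on an equally spaced grid of
levels over each factor's physical range; optimization happens over a
continuous box :class:`Region`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = ["Factor", "FactorSpace", "Region"]


@dataclass(frozen=True)
class Factor:
    """One controllable process variable with its physical range and grid.

    Parameters
    ----------
    name : str
        Factor name, e.g. ``"pH"``, ``"agitation"``, ``"aeration"``.
    low, high : float
        Physical range; ``low < high``.
    n_levels : int
        Number of equally spaced grid levels (>= 2).
    unit : str
        Physical unit ("" for dimensionless pH, "rpm", "vvm").
    """

    name: str
    low: float
    high: float
    n_levels: int
    unit: str = ""

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"factor {self.name!r}: low must be < high")
        if self.n_levels < 2:
            raise ValueError(f"factor {self.name!r}: n_levels must be >= 2")

    @property
    def grid(self) -> np.ndarray:
        """Equally spaced level grid; level k (1-based) maps to
        ``low + (k-1)*(high-low)/(n_levels-1)``."""
        return np.linspace(self.low, self.high, self.n_levels)

    def physical(self, level: int | np.ndarray) -> np.ndarray:
        """Physical value(s) for 1-based level index(es)."""
        level = np.asarray(level)
        if np.any((level < 1) | (level > self.n_levels)):
            raise ValueError(
                f"factor {self.name!r}: levels must lie in 1..{self.n_levels}"
            )
        return self.low + (level - 1) * (self.high - self.low) / (self.n_levels - 1)

    def level_of(self, value: float) -> int:
        """Nearest 1-based level index of a physical value on the grid."""
        k = int(round((value - self.low) / (self.high - self.low) * (self.n_levels - 1))) + 1
        return min(max(k, 1), self.n_levels)


@dataclass(frozen=True)
class FactorSpace:
    """Ordered collection of factors defining the experimental space."""

    factors: tuple[Factor, ...]

    def __init__(self, factors: Iterable[Factor]):
        object.__setattr__(self, "factors", tuple(factors))
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise ValueError("factor names must be unique")

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.factors]

    def __getitem__(self, name: str) -> Factor:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(name)

    def __len__(self) -> int:
        return len(self.factors)

    def physical_matrix(self, level_matrix: np.ndarray) -> np.ndarray:
        """Map an ``n_runs x n_factors`` matrix of 1-based level indices to
        physical units, column by column."""
        level_matrix = np.asarray(level_matrix)
        if level_matrix.shape[1] != len(self.factors):
            raise ValueError("level matrix has wrong number of columns")
        cols = [f.physical(level_matrix[:, j]) for j, f in enumerate(self.factors)]
        return np.column_stack(cols)

    def region(self) -> "Region":
        """Bounding box of the full factor space."""
        return Region({f.name: (f.low, f.high) for f in self.factors})


@dataclass(frozen=True)
class Region:
    """A box region (per-factor physical bounds) for optimization."""

    bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"region bound for {name!r}: low must be < high")
        if not self.bounds:
            raise ValueError("region must bound at least one factor")

    @property
    def names(self) -> list[str]:
        return list(self.bounds.keys())

    def contains(self, settings: Mapping[str, float], atol: float = 1e-9) -> bool:
        return all(
            lo - atol <= settings[name] <= hi + atol
            for name, (lo, hi) in self.bounds.items()
        )

    def clip(self, settings: Mapping[str, float]) -> dict[str, float]:
        return {
            name: float(min(max(settings[name], lo), hi))
            for name, (lo, hi) in self.bounds.items()
        }
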