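"""Uniform experimental designs by the good-lattice-point (GLP) method.

A uniform design U_n(n^s) spreads n runs over an n-level grid in s factors
so that the points fill the factor space as evenly as possible.  Candidate
designs are generated number-theoretically: column k is the residue sequence
``(i * h_k) mod n`` for a generator h_k coprime to n (residue 0 written as
n), so every column is a permutation of 1..n.  Because the plain GLP family
can be poor for some n, the classical *leave-one-out* variant is also
enumerated: generate an (n+1)-run GLP design from generators coprime to
n+1 and delete the final run (the all-(n+1) row), leaving an n-run design
on levels 1..n.  Among all admissible generator subsets from both
constructions, the design minimizing the centered L2 discrepancy is
returned; ties go to the base construction and then to the
lexicographically smallest generator vector, so generation is fully
deterministic.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .factors import FactorSpace

__all__ = ["DesignTable", "make_uniform_design", "centered_l2_discrepancy"]


@dataclass(frozen=True)
class DesignTable:
    """An n_runs x n_factors design in level-index and physical form.

    ``level_matrix`` holds 1-based level indices; ``physical_matrix`` the
    corresponding physical settings (requires an attached
    :class:`~fermopt.factors.FactorSpace`).  ``provenance`` records whether
    the table was generated or ships as a packaged fixture.
    """

    level_matrix: np.ndarray
    space: Optional[FactorSpace] = None
    provenance: str = "generated"

    def __post_init__(self) -> None:
        lm = np.asarray(self.level_matrix, dtype=int)
        object.__setattr__(self, "level_matrix", lm)
        if lm.ndim != 2:
            raise ValueError("level_matrix must be 2-D")
        if self.space is not None and len(self.space) != lm.shape[1]:
            raise ValueError("factor space does not match design columns")

    @property
    def n_runs(self) -> int:
        return self.level_matrix.shape[0]

    @property
    def n_factors(self) -> int:
        return self.level_matrix.shape[1]

    @property
    def physical_matrix(self) -> np.ndarray:
        if self.space is None:
            raise ValueError("design has no attached factor space")
        return self.space.physical_matrix(self.level_matrix)

    def with_space(self, space: FactorSpace) -> "DesignTable":
        return DesignTable(self.level_matrix, space, self.provenance)

    def settings(self, row: int) -> dict[str, float]:
        """Physical settings of one run as a name -> value mapping."""
        if self.space is None:
            raise ValueError("design has no attached factor space")
        phys = self.physical_matrix[row]
        return {f.name: float(v) for f, v in zip(self.space.factors, phys)}


def centered_l2_discrepancy(level_matrix: np.ndarray, n_levels: int | None = None) -> float:
    """Centered L2 discrepancy (CD2) of a design on an n-level grid.

    Levels k in 1..n are mapped to the unit-cube midpoints
    x = (k - 0.5)/n and Hickernell's CD2 formula is evaluated.  Lower means
    more uniform.
    """
    U = np.asarray(level_matrix, dtype=float)
    if U.ndim != 2:
        raise ValueError("level matrix must be 2-D")
    n, s = U.shape
    if n_levels is None:
        n_levels = int(U.max())
    x = (U - 0.5) / n_levels
    d = np.abs(x - 0.5)
    term1 = (13.0 / 12.0) ** s
    term2 = (2.0 / n) * np.sum(np.prod(1 + 0.5 * d - 0.5 * d**2, axis=1))
    # pairwise product term, vectorized over the (n, n) pair grid
    di = d[:, None, :]
    dj = d[None, :, :]
    dist = np.abs(x[:, None, :] - x[None, :, :])
    term3 = np.sum(np.prod(1 + 0.5 * di + 0.5 * dj - 0.5 * dist, axis=2)) / n**2
    return float(np.sqrt(term1 - term2 + term3))


def _glp_column(h: int, n: int) -> np.ndarray:
    col = (np.arange(1, n + 1) * h) % n
    col[col == 0] = n
    return col


def _coprime_generators(n: int) -> list[int]:
    return [h for h in range(1, n) if math.gcd(h, n) == 1]


def _candidate_designs(n_runs: int, n_factors: int):
    """Yield (level_matrix, construction_rank, generators) candidates.

    construction_rank 0 = base GLP from n_runs, 1 = leave-one-out from
    n_runs + 1; used as the first tie-break key.
    """
    base = _coprime_generators(n_runs)
    if len(base) >= n_factors:
        for combo in itertools.combinations(base, n_factors):
            cols = [_glp_column(h, n_runs) for h in combo]
            yield np.column_stack(cols), 0, combo
    loo = _coprime_generators(n_runs + 1)
    if len(loo) >= n_factors:
        for combo in itertools.combinations(loo, n_factors):
            cols = [_glp_column(h, n_runs + 1)[:n_runs] for h in combo]
            yield np.column_stack(cols), 1, combo


def make_uniform_design(n_runs: int, n_factors: int) -> DesignTable:
    """Construct the good-lattice-point uniform design U_{n_runs}(n_runs^{n_factors}).

    Enumerates every admissible generator subset of the base and
    leave-one-out constructions and returns the candidate with minimal
    centered L2 discrepancy.  Deterministic: ties are broken in favour of
    the base construction, then by the lexicographically smallest generator
    vector.

    Raises
    ------
    ValueError
        If ``n_factors >= n_runs``, ``n_runs > 50``, or the requested number
        of factors exceeds the admissible generator count of both
        constructions.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    if n_factors < 1:
        raise ValueError("n_factors must be >= 1")
    if n_factors >= n_runs:
        raise ValueError("n_factors must be smaller than n_runs")
    if n_runs > 50:
        raise ValueError("n_runs > 50 is outside the supported desk scale")

    max_cols = max(len(_coprime_generators(n_runs)), len(_coprime_generators(n_runs + 1)))
    if n_factors > max_cols:
        raise ValueError(
            f"at most {max_cols} factors are supported for {n_runs} runs "
            "(number of admissible good-lattice generators)"
        )

    best = None
    for levels, rank, combo in _candidate_designs(n_runs, n_factors):
        disc = centered_l2_discrepancy(levels, n_runs)
        key = (round(disc, 12), rank, combo)
        if best is None or key < best[0]:
            best = (key, levels)
    assert best is not None
    return DesignTable(best[1], provenance="generated")
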