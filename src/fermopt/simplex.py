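"""Rotating-simplex sequential experiment protocol.

For k factors the simplex is a set of k+1 trial runs.  After each batch the
worst run is discarded and replaced by its reflection through the centroid
of the remaining ("best") runs:

    R_new = 2 * mean(best runs) - R_worst

The loop stops when a newly proposed run fails to improve on the best
response of the simplex it was reflected from.  Only the reflection move is
implemented — the full Nelder–Mead expansion/contraction repertoire is out
of scope for this protocol.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .factors import Region
from .records import RunRecord

__all__ = [
    "SimplexProposal",
    "propose_simplex_point",
    "select_worst",
    "simplex_should_stop",
]


@dataclass(frozen=True)
class SimplexProposal:
    """Reflected settings plus an out-of-bounds flag (no clipping applied)."""

    settings: dict[str, float]
    out_of_bounds: bool = False


def propose_simplex_point(
    runs: Sequence[RunRecord],
    worst_index: int,
    region: Optional[Region] = None,
) -> SimplexProposal:
    """Reflect the worst vertex of a simplex of trial runs.

    ``runs`` must contain exactly k+1 runs for a k-factor problem with
    identical factor names.  The proposal is component-wise
    ``2*mean(best) - worst`` in physical units.  Proposals falling outside
    ``region`` (if given) are flagged, never clipped: the protocol follows
    wherever the response surface leads.
    """
    if not runs:
        raise ValueError("no runs supplied")
    names = list(runs[0].settings.keys())
    k = len(names)
    if len(runs) != k + 1:
        raise ValueError(
            f"simplex size must be n_factors + 1 = {k + 1}, got {len(runs)} runs"
        )
    for r in runs:
        if list(r.settings.keys()) != names:
            raise ValueError("all runs must share identical factor names")
    if not 0 <= worst_index < len(runs):
        raise ValueError("worst_index out of range")

    best = [r for i, r in enumerate(runs) if i != worst_index]
    worst = runs[worst_index]
    settings = {
        name: 2.0 * sum(r.settings[name] for r in best) / len(best)
        - worst.settings[name]
        for name in names
    }
    oob = region is not None and not region.contains(settings)
    return SimplexProposal(settings=settings, out_of_bounds=oob)


def select_worst(runs: Sequence[RunRecord], response_name: str) -> int:
    """Index of the run with the minimum value of the named response.

    Ties are broken by the lowest ``run_id``.
    """
    if not runs:
        raise ValueError("no runs supplied")
    vals = [r.response_value(response_name) for r in runs]
    order = sorted(range(len(runs)), key=lambda i: (vals[i], runs[i].run_id))
    return order[0]


def simplex_should_stop(history: Sequence[RunRecord], response_name: str) -> bool:
    """True when the newest run does not improve on the preceding simplex.

    ``history`` is the executed runs in order; the final entry is the most
    recent reflection proposal.  Equality counts as no improvement.
    """
    k = len(history[-1].settings)
    if len(history) < k + 2:
        raise ValueError(
            f"need at least n_factors + 2 = {k + 2} runs to assess stopping"
        )
    newest = history[-1].response_value(response_name)
    preceding = history[-(k + 2) : -1]
    best_prev = max(r.response_value(response_name) for r in preceding)
    return newest <= best_prev
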