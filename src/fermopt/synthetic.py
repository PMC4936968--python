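"""Synthetic fermentation response generator.

Emulates the statistical structure the analysis assumes: each response is a
linear-plus-pairwise-interaction surface in the coded factors with additive
Gaussian noise on the coded scale.  The default ground truth is the
published coefficient set of the xylitol study, so a noise-free simulated
campaign refits to exactly those coefficients.  No fermentation kinetics
are simulated — these are endpoint responses only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .design import DesignTable
from .modeling import DEFAULT_CODING, CodedModel, CodingScheme
from .records import Response, RunRecord

__all__ = ["TrueSurface", "default_surface", "simulate_run", "generate_design_responses"]


@dataclass(frozen=True)
class TrueSurface:
    """Ground-truth response surfaces on the coded scale.

    ``coefficients`` maps response name to the ordered coded coefficient
    vector (b0, linear..., interactions...); ``noise_sd`` is the additive
    Gaussian standard deviation per response, in coded units (0 gives exact
    surface values).
    """

    factor_names: tuple[str, ...]
    coefficients: Mapping[str, np.ndarray]
    noise_sd: Mapping[str, float]
    coding: CodingScheme = DEFAULT_CODING

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "coefficients", {k: np.asarray(v, float) for k, v in self.coefficients.items()}
        )
        object.__setattr__(self, "noise_sd", dict(self.noise_sd))
        for name, sd in self.noise_sd.items():
            if not np.isfinite(sd) or sd < 0:
                raise ValueError(f"noise_sd for {name!r} must be finite and >= 0")

    @property
    def response_names(self) -> list[str]:
        return list(self.coefficients.keys())

    def model(self, response_name: str) -> CodedModel:
        """The surface as a (coefficient-only) CodedModel, e.g. for optimization."""
        return CodedModel(
            response_name=response_name,
            factor_names=self.factor_names,
            beta=self.coefficients[response_name],
            include_squared=False,
            coding=self.coding,
        )

    def evaluate(self, response_name: str, settings: Mapping[str, float]) -> float:
        """Noise-free physical response value at physical settings."""
        m = self.model(response_name)
        return float(self.coding.decode(response_name, m.predict_coded(settings)))


def default_surface(noise_sd: float | Mapping[str, float] = 0.01) -> TrueSurface:
    """Ground truth mirroring the published xylitol study's coded
    regression equations, with 0.01 coded-unit noise per response (the
    study's replicate SDs were <= 0.006)."""
    from .datasets import published_models  # local import avoids a cycle

    models = published_models()
    if isinstance(noise_sd, (int, float)):
        noise = {name: float(noise_sd) for name in models}
    else:
        noise = dict(noise_sd)
    return TrueSurface(
        factor_names=("pH", "agitation", "aeration"),
        coefficients={name: m.beta for name, m in models.items()},
        noise_sd=noise,
    )


def simulate_run(
    surface: TrueSurface,
    settings: Mapping[str, float],
    seed: int,
    run_id: int = 1,
) -> RunRecord:
    """Simulate one experiment: surface value plus coded Gaussian noise,
    decoded to physical units and truncated at zero (negative responses are
    unphysical; truncated responses are flagged).  Reproducible for a fixed
    seed."""
    rng = np.random.default_rng(seed)
    responses: dict[str, Response] = {}
    flags: list[str] = []
    for name in surface.response_names:
        coded = surface.model(name).predict_coded(settings)
        coded += rng.normal(0.0, surface.noise_sd[name])
        value = float(surface.coding.decode(name, coded))
        if value < 0:
            value = 0.0
            flags.append(f"truncated:{name}")
        responses[name] = Response(
            mean=value, sd=float(surface.coding.decode(name, surface.noise_sd[name]))
        )
    return RunRecord(
        run_id=run_id, settings=dict(settings), responses=responses, flags=tuple(flags)
    )


def generate_design_responses(
    surface: TrueSurface, design: DesignTable, seed: int
) -> list[RunRecord]:
    """One simulated run per design row, sub-seeded as ``seed + row index``
    so every row is individually reproducible."""
    records = []
    for i in range(design.n_runs):
        records.append(
            simulate_run(surface, design.settings(i), seed=seed + i, run_id=i + 1)
        )
    return records
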