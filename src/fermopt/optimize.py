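"""Individual and simultaneous response optimization over the factor box.

Individual optima maximize one fitted response surface over a box region.
Simultaneous optimization minimizes the generalized distance

    rho(Y(x), Phi) = sqrt( sum_i (Y_i(x) - Phi_i)^2 )

between the vector of coded predicted responses Y(x) and the vector Phi of
individually attained optima.  Working on the coded response scale keeps
xylitol concentration (tens of g/L) from dominating the other responses.

Both searches use a deterministic exhaustive grid scan followed by a local
L-BFGS-B polish from the best grid cell, so results are reproducible and
ties resolve to the lexicographically smallest location.

Khuri–Conlon rectangular confidence intervals around each individual
optimum are built from the error mean square, the design information
matrix (X0' X0)^-1 and the model-term vector z(xi) at the optimum:

    half-width = sqrt( z' (X0'X0)^-1 z ) * sqrt(MS) * t_{alpha/2, N-p}
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import optimize as sopt
from scipy import stats

from .design import DesignTable
from .factors import Region
from .modeling import CodedModel, CodingScheme, model_matrix

__all__ = [
    "DEFAULT_GRID_STEPS",
    "IndividualOptimum",
    "SimultaneousOptimum",
    "ConfidenceInterval",
    "maximize_individual",
    "distance",
    "minimize_distance",
    "khuri_conlon_interval",
]

#: Default physical grid steps per factor for the exhaustive scan.
DEFAULT_GRID_STEPS = {"pH": 0.1, "agitation": 10.0, "aeration": 0.1}


@dataclass(frozen=True)
class IndividualOptimum:
    """Location and value of one response's box-constrained maximum."""

    response_name: str
    location: dict[str, float]
    value: float  # physical response units


@dataclass(frozen=True)
class SimultaneousOptimum:
    """Generalized-distance minimizer with per-response predictions."""

    location: dict[str, float]
    predicted: dict[str, float]  # physical response units
    distance: float  # coded response scale


@dataclass(frozen=True)
class ConfidenceInterval:
    """Rectangular (per-response) confidence bounds around an optimum."""

    response_name: str
    gamma1: float
    gamma2: float
    alpha: float


def _grid_axes(region: Region, steps: Optional[Mapping[str, float]] = None) -> list[np.ndarray]:
    axes = []
    for name, (lo, hi) in region.bounds.items():
        step = (steps or {}).get(name, DEFAULT_GRID_STEPS.get(name, (hi - lo) / 50.0))
        n = int(round((hi - lo) / step))
        ax = lo + step * np.arange(n + 1)
        ax[-1] = min(ax[-1], hi)
        axes.append(ax)
    return axes


def _grid_points(region: Region, steps=None) -> np.ndarray:
    """All grid points in lexicographic order, shape (n_points, n_factors)."""
    axes = _grid_axes(region, steps)
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.column_stack([m.ravel() for m in mesh])


def _settings_dict(region: Region, x: np.ndarray) -> dict[str, float]:
    return {name: float(v) for name, v in zip(region.names, x)}


def _polish(region: Region, x0: np.ndarray, objective) -> np.ndarray:
    """Box-constrained local refinement (minimization) from a grid start."""
    bounds = [region.bounds[name] for name in region.names]
    res = sopt.minimize(
        objective, x0, method="L-BFGS-B", bounds=bounds,
        options={"ftol": 1e-18, "gtol": 1e-12, "maxiter": 500},
    )
    return res.x if res.fun <= objective(x0) else x0


def maximize_individual(
    model: CodedModel,
    region: Region,
    steps: Optional[Mapping[str, float]] = None,
) -> IndividualOptimum:
    """Global maximum of the predicted response over the box.

    Deterministic grid scan (first occurrence of the maximum, i.e. the
    lexicographically smallest tied location) followed by a local polish.
    The polished value can only improve on the grid value.
    """
    pts = _grid_points(region, steps)
    vals = _predict_coded_batch(model, region.names, pts)
    i = int(np.argmax(vals))

    def neg(x: np.ndarray) -> float:
        return -float(_predict_coded_batch(model, region.names, x[None, :])[0])

    x = _polish(region, pts[i], neg)
    loc = _settings_dict(region, x)
    value = float(model.coding.decode(model.response_name, model.predict_coded(loc)))
    return IndividualOptimum(model.response_name, loc, value)


def _predict_coded_batch(model: CodedModel, names: Sequence[str], pts: np.ndarray) -> np.ndarray:
    order = [list(names).index(f) for f in model.factor_names]
    coded = np.column_stack(
        [model.coding.encode(f, pts[:, j]) for f, j in zip(model.factor_names, order)]
    )
    return model_matrix(coded, model.include_squared) @ model.beta


def distance(
    Y: Mapping[str, float],
    Phi: Mapping[str, float],
    coding: CodingScheme,
) -> float:
    """Generalized distance rho between predicted responses Y and the
    individual optima Phi, on the coded response scale.  Inputs are in
    physical units."""
    if set(Y) != set(Phi):
        raise ValueError("Y and Phi must carry the same response names")
    diffs = [
        float(coding.encode(name, Y[name])) - float(coding.encode(name, Phi[name]))
        for name in sorted(Y)
    ]
    return float(np.sqrt(np.sum(np.square(diffs))))


def minimize_distance(
    models: Mapping[str, CodedModel],
    optima: Mapping[str, "IndividualOptimum | float"],
    region: Region,
    steps: Optional[Mapping[str, float]] = None,
) -> SimultaneousOptimum:
    """Minimize the generalized distance over the box.

    ``optima`` supplies Phi per response, either as
    :class:`IndividualOptimum` objects or as plain physical values.  Uses
    the same deterministic grid + polish scheme as
    :func:`maximize_individual`; the polish minimizes the smooth squared
    distance.
    """
    if set(models) != set(optima):
        raise ValueError("models and optima must cover the same response names")
    names = sorted(models)
    phi = np.array(
        [
            float(
                models[n].coding.encode(
                    n, optima[n].value if isinstance(optima[n], IndividualOptimum) else optima[n]
                )
            )
            for n in names
        ]
    )

    pts = _grid_points(region, steps)
    preds = np.column_stack([_predict_coded_batch(models[n], region.names, pts) for n in names])
    d2 = np.sum((preds - phi) ** 2, axis=1)
    i = int(np.argmin(d2))

    def obj(x: np.ndarray) -> float:
        p = np.array([_predict_coded_batch(models[n], region.names, x[None, :])[0] for n in names])
        return float(np.sum((p - phi) ** 2))

    x = _polish(region, pts[i], obj)
    loc = _settings_dict(region, x)
    predicted = {
        n: float(models[n].coding.decode(n, models[n].predict_coded(loc))) for n in names
    }
    # rho on the coded response scale, each response under its own coding
    rho = float(np.sqrt(obj(x)))
    return SimultaneousOptimum(location=loc, predicted=predicted, distance=rho)


def khuri_conlon_interval(
    model: CodedModel,
    optimum: IndividualOptimum,
    design: Optional[DesignTable] = None,
    alpha: float = 0.10,
) -> ConfidenceInterval:
    """Rectangular confidence interval around an individual optimum.

    g = sqrt(z(xi)' (X0'X0)^-1 z(xi)) with X0 the full n x p coded model
    matrix of the fit and z(xi) the model-term vector at the optimum;
    half-width = g * sqrt(MS) * t_{alpha/2, N-p}, decoded to physical
    units.  The interval is symmetric about the optimum value by
    construction.
    """
    X0 = model.design_matrix
    if X0.size == 0:
        raise ValueError("model carries no design matrix (not a fitted model)")
    if design is not None and design.n_runs != X0.shape[0]:
        raise ValueError("design table does not match the fitted model's run count")
    n, p = X0.shape
    if n - p < 1:
        raise ValueError("Khuri-Conlon interval needs error degrees of freedom >= 1")
    xtx = X0.T @ X0
    if np.linalg.cond(xtx) > 1e12:
        raise ValueError("X0'X0 is singular or near-singular")
    z = model.term_vector(optimum.location)
    g = float(np.sqrt(z @ np.linalg.solve(xtx, z)))
    ms = model.mean_square_error
    t = float(stats.t.ppf(1 - alpha / 2, n - p))
    half_coded = g * np.sqrt(ms) * t
    half = float(model.coding.decode(model.response_name, half_coded))
    return ConfidenceInterval(
        response_name=model.response_name,
        gamma1=optimum.value - half,
        gamma2=optimum.value + half,
        alpha=alpha,
    )
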