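"""Coded interaction-regression modelling of fermentation responses.

Each response y is modelled on a *coded* scale by ordinary least squares:

    y = b0 + sum_i b_i x_i + sum_{i<j} b_ij x_i x_j   (+ squares, optional)

Coding rescales factors and responses so coefficients are comparable in
magnitude: agitation enters as rpm/100 and xylitol concentration as
(g/L)/100, while pH, aeration (vvm), productivity and yield are used as-is.
This particular scheme is load-bearing — it is the scale on which the
published coefficient sets, ANOVA sums of squares and the generalized
distance function all operate — and is exposed as :data:`DEFAULT_CODING`.

Reporting convention for three factors: coefficients are ordered
(b0, b1, b2, b3, b12, b23, b31).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .design import DesignTable
from .records import RunRecord

__all__ = [
    "CodingScheme",
    "DEFAULT_CODING",
    "CodedModel",
    "AnovaTable",
    "code",
    "fit_interaction_model",
    "predict",
    "anova",
    "percentage_correlation",
    "response_metrics",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class CodingScheme:
    """Per-name positive divisors mapping physical values to coded values.

    encode: coded = physical / divisor;  decode: physical = coded * divisor.
    The two are exact inverses.
    """

    factor_divisors: Mapping[str, float]
    response_divisors: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "factor_divisors", dict(self.factor_divisors))
        object.__setattr__(self, "response_divisors", dict(self.response_divisors))
        for d in (*self.factor_divisors.values(), *self.response_divisors.values()):
            if not d > 0:
                raise ValueError("coding divisors must be strictly positive")

    def _divisor(self, name: str) -> float:
        if name in self.factor_divisors:
            return self.factor_divisors[name]
        if name in self.response_divisors:
            return self.response_divisors[name]
        raise KeyError(f"no coding divisor defined for {name!r}")

    def encode(self, name: str, value):
        return np.asarray(value, dtype=float) / self._divisor(name)

    def decode(self, name: str, value):
        return np.asarray(value, dtype=float) * self._divisor(name)

    def encode_settings(self, settings: Mapping[str, float]) -> dict[str, float]:
        return {k: float(self.encode(k, v)) for k, v in settings.items()}


#: Coding used throughout: x2 = rpm/100, y2 = concentration/100, rest unscaled.
DEFAULT_CODING = CodingScheme(
    factor_divisors={"pH": 1.0, "agitation": 100.0, "aeration": 1.0},
    response_divisors={"productivity": 1.0, "concentration": 100.0, "yield": 1.0},
)


def code(values: Mapping[str, float], scheme: CodingScheme, direction: str = "encode") -> dict[str, float]:
    """Encode (physical -> coded) or decode (coded -> physical) named values."""
    if direction not in ("encode", "decode"):
        raise ValueError("direction must be 'encode' or 'decode'")
    fn = scheme.encode if direction == "encode" else scheme.decode
    return {k: float(fn(k, v)) for k, v in values.items()}


def _interaction_pairs(k: int) -> list[tuple[int, int]]:
    # three factors follow the field's (1,2),(2,3),(3,1) reporting order;
    # other dimensions fall back to combinations
    if k == 3:
        return [(0, 1), (1, 2), (2, 0)]
    return list(itertools.combinations(range(k), 2))


def term_names(factor_names: Sequence[str], include_squared: bool = False) -> list[str]:
    names = ["intercept"] + list(factor_names)
    names += [
        f"{factor_names[i]}*{factor_names[j]}"
        for i, j in _interaction_pairs(len(factor_names))
    ]
    if include_squared:
        names += [f"{n}^2" for n in factor_names]
    return names


def model_matrix(coded_settings: np.ndarray, include_squared: bool = False) -> np.ndarray:
    """Build the coded model matrix: intercept, linear, pairwise interaction
    columns (and squares when requested)."""
    X = np.atleast_2d(np.asarray(coded_settings, dtype=float))
    n, k = X.shape
    cols = [np.ones(n)] + [X[:, i] for i in range(k)]
    cols += [X[:, i] * X[:, j] for i, j in _interaction_pairs(k)]
    if include_squared:
        cols += [X[:, i] ** 2 for i in range(k)]
    return np.column_stack(cols)


@dataclass(frozen=True)
class CodedModel:
    """Fitted coefficient set for one response on the coded scale.

    ``beta`` is ordered (b0, linear..., interactions..., squares...).
    ``design_matrix`` is the full coded n x p model matrix the fit used,
    retained for ANOVA and Khuri–Conlon interval construction.
    """

    response_name: str
    factor_names: tuple[str, ...]
    beta: np.ndarray
    include_squared: bool
    coding: CodingScheme
    observed: np.ndarray = field(default_factory=lambda: np.empty(0))
    fitted_values: np.ndarray = field(default_factory=lambda: np.empty(0))
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))
    design_matrix: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    factor_ranges: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def beta0(self) -> float:
        return float(self.beta[0])

    @property
    def beta_linear(self) -> np.ndarray:
        return self.beta[1 : 1 + len(self.factor_names)]

    @property
    def beta_interaction(self) -> np.ndarray:
        k = len(self.factor_names)
        npairs = len(_interaction_pairs(k))
        return self.beta[1 + k : 1 + k + npairs]

    @property
    def beta_squared(self) -> Optional[np.ndarray]:
        if not self.include_squared:
            return None
        return self.beta[-len(self.factor_names) :]

    @property
    def n_params(self) -> int:
        return len(self.beta)

    @property
    def df_error(self) -> int:
        return len(self.observed) - self.n_params

    @property
    def mean_square_error(self) -> float:
        """Error mean square MS on the coded scale (requires df_error >= 1)."""
        if self.df_error < 1:
            raise ValueError("model has no error degrees of freedom")
        return float(np.sum(self.residuals**2) / self.df_error)

    def term_vector(self, settings: Mapping[str, float]) -> np.ndarray:
        """Full model-term vector z(x) at *physical* settings (coded internally)."""
        coded = [self.coding.encode(n, settings[n]) for n in self.factor_names]
        return model_matrix(np.array(coded)[None, :], self.include_squared)[0]

    def predict_coded(self, settings: Mapping[str, float]) -> float:
        return float(self.term_vector(settings) @ self.beta)


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Heuristically name the columns involved in a rank deficiency."""
    rank = np.linalg.matrix_rank(X)
    bad = []
    for j in range(X.shape[1]):
        keep = [c for c in range(X.shape[1]) if c != j]
        if np.linalg.matrix_rank(X[:, keep]) == rank:
            bad.append(names[j])
    return bad or list(names)


def fit_interaction_model(
    design: Optional[DesignTable],
    records: Sequence[RunRecord],
    response_name: str,
    include_squared: bool = False,
    coding: CodingScheme = DEFAULT_CODING,
) -> CodedModel:
    """Ordinary least squares fit of the coded interaction model.

    Settings are taken from the run records (the design argument, when
    given, must agree with them and mainly documents provenance).  With
    three factors and squares excluded the model has p = 7 parameters, so
    eight runs leave a single error degree of freedom.
    """
    if not records:
        raise ValueError("no run records supplied")
    factor_names = tuple(records[0].settings.keys())
    k = len(factor_names)
    p = 1 + k + len(_interaction_pairs(k)) + (k if include_squared else 0)
    n = len(records)
    if include_squared and p > n:
        raise ValueError(
            f"squared terms give p = {p} parameters but only n = {n} runs; "
            "the full quadratic is unfittable on this design"
        )
    if p > n:
        raise ValueError(f"p = {p} parameters exceed n = {n} runs")

    phys = np.array([[r.settings[f] for f in factor_names] for r in records])
    if design is not None and design.space is not None:
        if not np.allclose(design.physical_matrix, phys):
            raise ValueError("design table does not match the run records' settings")

    coded = np.column_stack(
        [coding.encode(f, phys[:, j]) for j, f in enumerate(factor_names)]
    )
    X = model_matrix(coded, include_squared)
    names = term_names(factor_names, include_squared)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "model matrix is rank deficient; collinear columns: "
            + ", ".join(_collinear_columns(X, names))
        )

    y = coding.encode(response_name, np.array([r.response_value(response_name) for r in records]))
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    ranges = {f: (float(phys[:, j].min()), float(phys[:, j].max())) for j, f in enumerate(factor_names)}
    return CodedModel(
        response_name=response_name,
        factor_names=factor_names,
        beta=beta,
        include_squared=include_squared,
        coding=coding,
        observed=y,
        fitted_values=fitted,
        residuals=y - fitted,
        design_matrix=X,
        factor_ranges=ranges,
    )


def predict(model: CodedModel, settings: Mapping[str, float]) -> float:
    """Evaluate the coded polynomial at physical settings, decoded to
    physical response units.  Extrapolation outside the fitted design's
    factor ranges is permitted but raises a UserWarning."""
    for name, (lo, hi) in model.factor_ranges.items():
        v = settings[name]
        if v < lo - 1e-9 or v > hi + 1e-9:
            warnings.warn(
                f"predicting outside the fitted range of {name!r} "
                f"({v} not in [{lo}, {hi}]): extrapolation",
                UserWarning,
                stacklevel=2,
            )
    return float(model.coding.decode(model.response_name, model.predict_coded(settings)))


@dataclass(frozen=True)
class AnovaTable:
    """Regression / error / total decomposition on the coded scale.

    ``f`` and ``p`` are NaN markers when the error degrees of freedom are
    zero (a saturated fit).
    """

    df_regression: int
    df_error: int
    df_total: int
    ss_regression: float
    ss_error: float
    ss_total: float
    ms_regression: float
    ms_error: float
    f: float
    p: float


def anova(model: CodedModel) -> AnovaTable:
    """ANOVA for a fitted coded model: corrected total SS split into
    regression and error, with the F upper-tail p-value."""
    y = model.observed
    if y.size == 0:
        raise ValueError("model carries no observations")
    n = len(y)
    ss_total = float(np.sum((y - y.mean()) ** 2))
    ss_error = float(np.sum(model.residuals**2))
    ss_reg = ss_total - ss_error
    df_reg = model.n_params - 1
    df_err = n - model.n_params
    ms_reg = ss_reg / df_reg if df_reg else np.nan
    if df_err >= 1:
        ms_err = ss_error / df_err
        f = ms_reg / ms_err if ms_err > 0 else np.inf
        p = float(stats.f.sf(f, df_reg, df_err))
    else:
        ms_err = f = p = np.nan
    return AnovaTable(df_reg, df_err, n - 1, ss_reg, ss_error, ss_total, ms_reg, ms_err, f, p)


def percentage_correlation(observed, predicted) -> float:
    """100 x Pearson product-moment correlation between observed and
    predicted response vectors."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("observed and predicted must be equal-length vectors of size >= 2")
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        raise ValueError("percentage correlation undefined for zero-variance input")
    return float(100.0 * np.corrcoef(obs, pred)[0, 1])


def response_metrics(
    xylitol_g_per_L: float, xylose_consumed_g_per_L: float, time_h: float
) -> tuple[float, float]:
    """(yield g/g, productivity g/L/h) from endpoint measurements:
    yield = xylitol produced / xylose consumed, productivity = xylitol / time."""
    if xylose_consumed_g_per_L <= 0:
        raise ValueError("xylose consumed must be positive")
    if time_h <= 0:
        raise ValueError("fermentation time must be positive")
    return (
        xylitol_g_per_L / xylose_consumed_g_per_L,
        xylitol_g_per_L / time_h,
    )


def save_model(model: CodedModel, path) -> None:
    """Export a fitted model as a flat key-value text file (bit-exact floats
    via repr) so downstream optimization runs are reproducible."""
    lines = [f"response={model.response_name}"]
    lines.append("factors=" + ",".join(model.factor_names))
    lines.append(f"include_squared={int(model.include_squared)}")
    for f in model.factor_names:
        lines.append(f"factor_divisor.{f}={model.coding.factor_divisors[f]!r}")
    lines.append(
        f"response_divisor.{model.response_name}="
        f"{model.coding.response_divisors[model.response_name]!r}"
    )
    for name, b in zip(term_names(model.factor_names, model.include_squared), model.beta):
        lines.append(f"beta.{name}={float(b)!r}")
    for f, (lo, hi) in model.factor_ranges.items():
        lines.append(f"range.{f}={lo!r},{hi!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_model(path) -> CodedModel:
    """Load a model written by :func:`save_model`."""
    kv: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and "=" in line:
                k, v = line.split("=", 1)
                kv[k] = v
    factor_names = tuple(kv["factors"].split(","))
    include_squared = bool(int(kv["include_squared"]))
    response_name = kv["response"]
    coding = CodingScheme(
        factor_divisors={f: float(kv[f"factor_divisor.{f}"]) for f in factor_names},
        response_divisors={response_name: float(kv[f"response_divisor.{response_name}"])},
    )
    beta = np.array(
        [float(kv[f"beta.{t}"]) for t in term_names(factor_names, include_squared)]
    )
    ranges = {}
    for f in factor_names:
        if f"range.{f}" in kv:
            lo, hi = kv[f"range.{f}"].split(",")
            ranges[f] = (float(lo), float(hi))
    return CodedModel(
        response_name=response_name,
        factor_names=factor_names,
        beta=beta,
        include_squared=include_squared,
        coding=coding,
        factor_ranges=ranges,
    )
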