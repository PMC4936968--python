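"""End-to-end uniform-design analysis pipeline and report assembly.

One call runs the full chain on a campaign's run records: fit the three
coded interaction models, compute ANOVA, locate individual optima, build
Khuri–Conlon intervals, minimize the generalized distance for the
simultaneous optimum, and summarize percentage changes against a stated
baseline.  Every intermediate is logged and kept on the report object, so
every number in the rendered text is traceable.  Given identical inputs
and configuration the rendered report is byte-identical (all searches are
deterministic, all floats fixed-precision formatted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .factors import Region
from .modeling import (
    DEFAULT_CODING,
    AnovaTable,
    CodedModel,
    CodingScheme,
    anova,
    fit_interaction_model,
    percentage_correlation,
    predict,
)
from .optimize import (
    ConfidenceInterval,
    IndividualOptimum,
    SimultaneousOptimum,
    khuri_conlon_interval,
    maximize_individual,
    minimize_distance,
)
from .records import RunRecord

__all__ = ["PipelineConfig", "OptimaReport", "run_uniform_design_pipeline",
           "percentage_change", "render_report"]

log = logging.getLogger("fermopt")

_RESPONSES = ("productivity", "concentration", "yield")


def percentage_change(new: float, baseline: float) -> float:
    """100 * (new - baseline) / baseline."""
    if baseline == 0:
        raise ValueError("percentage change undefined for zero baseline")
    return 100.0 * (new - baseline) / baseline


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration for the uniform-design analysis chain.

    ``baselines`` are prior-study reference values for the percentage-change
    summary (they are data, not constants of the method).  ``phi_override``
    replaces the computed individual-optimum targets Phi in the distance
    minimization, and ``reference_location`` adds a row of model
    predictions at a fixed operating point to the report.
    """

    response_names: tuple[str, ...] = _RESPONSES
    coding: CodingScheme = DEFAULT_CODING
    alpha: float = 0.10
    include_squared: bool = False
    grid_steps: Optional[Mapping[str, float]] = None
    baselines: Optional[Mapping[str, float]] = None
    phi_override: Optional[Mapping[str, float]] = None
    reference_location: Optional[Mapping[str, float]] = None
    min_runs: int = 8


@dataclass(frozen=True)
class OptimaReport:
    """Everything the analysis computed, stage by stage."""

    models: dict[str, CodedModel]
    anova_tables: dict[str, AnovaTable]
    correlations: dict[str, float]
    individual_optima: dict[str, IndividualOptimum]
    confidence_intervals: dict[str, ConfidenceInterval]
    simultaneous: SimultaneousOptimum
    percentage_changes: dict[str, float] = field(default_factory=dict)
    reference_predictions: dict[str, float] = field(default_factory=dict)


def run_uniform_design_pipeline(
    records: Sequence[RunRecord],
    region: Region,
    config: PipelineConfig = PipelineConfig(),
) -> OptimaReport:
    """Fit, test, and optimize all responses of a uniform-design campaign."""
    if len(records) < config.min_runs:
        raise ValueError(
            f"pipeline needs at least {config.min_runs} runs, got {len(records)}"
        )

    models: dict[str, CodedModel] = {}
    anovas: dict[str, AnovaTable] = {}
    correlations: dict[str, float] = {}
    optima: dict[str, IndividualOptimum] = {}
    intervals: dict[str, ConfidenceInterval] = {}

    for name in config.response_names:
        try:
            m = fit_interaction_model(
                None, records, name,
                include_squared=config.include_squared, coding=config.coding,
            )
        except Exception as exc:  # noqa: BLE001 - annotate the stage
            raise type(exc)(f"[fit:{name}] {exc}") from exc
        models[name] = m
        anovas[name] = anova(m)
        correlations[name] = percentage_correlation(m.observed, m.fitted_values)
        log.info("fit %s: beta=%s", name, [round(float(b), 4) for b in m.beta])
        log.info("anova %s: SS_total=%.4f SS_error=%.4f F=%.2f p=%.3f",
                 name, anovas[name].ss_total, anovas[name].ss_error,
                 anovas[name].f, anovas[name].p)

        opt = maximize_individual(m, region, config.grid_steps)
        optima[name] = opt
        intervals[name] = khuri_conlon_interval(m, opt, alpha=config.alpha)
        log.info("individual optimum %s: %.4f at %s", name, opt.value, opt.location)

    phi: Mapping[str, "IndividualOptimum | float"]
    phi = dict(config.phi_override) if config.phi_override else optima
    simultaneous = minimize_distance(models, phi, region, config.grid_steps)
    log.info("simultaneous optimum: rho=%.4f at %s predictions %s",
             simultaneous.distance, simultaneous.location, simultaneous.predicted)

    changes: dict[str, float] = {}
    if config.baselines:
        for name, base in config.baselines.items():
            if name in simultaneous.predicted:
                changes[name] = percentage_change(simultaneous.predicted[name], base)

    reference: dict[str, float] = {}
    if config.reference_location:
        for name, m in models.items():
            reference[name] = predict(m, config.reference_location)

    return OptimaReport(
        models=models,
        anova_tables=anovas,
        correlations=correlations,
        individual_optima=optima,
        confidence_intervals=intervals,
        simultaneous=simultaneous,
        percentage_changes=changes,
        reference_predictions=reference,
    )


def _fmt_location(loc: Mapping[str, float]) -> str:
    parts = []
    for name, v in loc.items():
        digits = 0 if name == "agitation" else 1
        parts.append(f"{name}={v:.{digits}f}")
    return ", ".join(parts)


def render_report(report: OptimaReport) -> str:
    """Deterministic plain-text report mirroring the study's table layout:
    coefficients to 3 decimals, predictions to 2, sums of squares to 2."""
    lines: list[str] = ["# Multi-response optimization report", ""]
    lines.append("## Fitted coded models")
    for name, m in report.models.items():
        coeffs = ", ".join(f"{b:.3f}" for b in m.beta)
        lines.append(f"{name}: [{coeffs}]")
        lines.append(f"  percentage correlation (obs vs fitted): {report.correlations[name]:.1f}")
    lines.append("")
    lines.append("## ANOVA (coded scale)")
    for name, a in report.anova_tables.items():
        lines.append(
            f"{name}: DF=({a.df_regression},{a.df_error},{a.df_total}) "
            f"SS=({a.ss_regression:.2f},{a.ss_error:.2f},{a.ss_total:.2f}) "
            f"F={a.f:.2f} p={a.p:.2f}"
        )
    lines.append("")
    lines.append("## Individual optima with rectangular confidence intervals")
    for name, opt in report.individual_optima.items():
        ci = report.confidence_intervals[name]
        lines.append(
            f"{name}: {opt.value:.2f} at ({_fmt_location(opt.location)}); "
            f"{100 * (1 - ci.alpha):.0f}% CI [{ci.gamma1:.2f}, {ci.gamma2:.2f}]"
        )
    lines.append("")
    s = report.simultaneous
    lines.append("## Simultaneous optimum (generalized distance)")
    lines.append(f"location: {_fmt_location(s.location)}  (rho = {s.distance:.4f})")
    for name, v in s.predicted.items():
        lines.append(f"  predicted {name}: {v:.2f}")
    if report.reference_predictions:
        lines.append("")
        lines.append("## Predictions at the reference operating point")
        for name, v in report.reference_predictions.items():
            lines.append(f"  {name}: {v:.2f}")
    if report.percentage_changes:
        lines.append("")
        lines.append("## Percentage change vs baseline")
        for name, v in report.percentage_changes.items():
            lines.append(f"  {name}: {v:+.2f} %")
    return "\n".join(lines) + "\n"
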