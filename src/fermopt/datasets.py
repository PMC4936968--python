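"""Packaged study data: the rotating-simplex campaign, the U8(8^3) uniform
design with its measured responses, and the published regression models.

These are the printed records of a batch stirred-tank xylitol fermentation
study with Debaryomyces nepalensis: three controlled factors (pH, agitation
in rpm, aeration in vvm) and three endpoint responses (productivity in
g/L/h, xylitol concentration in g/L, yield in g/g).  Response values are
means of analytical duplicates with their standard deviations.
"""

from __future__ import annotations

import numpy as np

from .design import DesignTable
from .factors import Factor, FactorSpace, Region
from .modeling import DEFAULT_CODING, CodedModel
from .records import Response, RunRecord

__all__ = [
    "uniform_design_space",
    "table1_fixture",
    "table2_fixture",
    "table2_predicted",
    "published_models",
    "PRIOR_STUDY_BASELINES",
    "SIMULTANEOUS_OPTIMUM_SETTINGS",
    "PUBLISHED_INDIVIDUAL_OPTIMA",
]

#: Baseline reactor performance from the group's prior study at fixed
#: 350 rpm / 0.5 vvm, used as the reference for percentage-change summaries.
PRIOR_STUDY_BASELINES = {"productivity": 0.43, "concentration": 54.0, "yield": 0.64}

#: Operating point reported as the simultaneous optimum of the published study.
SIMULTANEOUS_OPTIMUM_SETTINGS = {"pH": 4.3, "agitation": 370.0, "aeration": 0.9}

#: Individually optimal predicted responses reported by the published study
#: (used as the target vector Phi for the generalized-distance analysis).
PUBLISHED_INDIVIDUAL_OPTIMA = {"productivity": 0.57, "concentration": 55.0, "yield": 0.54}

_RESPONSES = ("productivity", "concentration", "yield")


def uniform_design_space() -> FactorSpace:
    """Eight-level grids of the uniform-design campaign: pH 4.0–7.5 step
    0.5, agitation 200–550 rpm step 50, aeration 0.6–2.0 vvm step 0.2."""
    return FactorSpace(
        [
            Factor("pH", 4.0, 7.5, 8, ""),
            Factor("agitation", 200.0, 550.0, 8, "rpm"),
            Factor("aeration", 0.6, 2.0, 8, "vvm"),
        ]
    )


# rotating-simplex campaign: run, pH, rpm, vvm, (mean, sd) per response
_TABLE1 = [
    (1, 4.0, 300, 1.5, (0.58, 0.003), (49.9, 0.003), (0.47, 0.004)),
    (2, 6.0, 300, 0.5, (0.36, 0.001), (42.9, 0.001), (0.47, 0.003)),
    (3, 4.0, 500, 0.5, (0.32, 0.006), (26.5, 0.006), (0.27, 0.005)),
    (4, 6.0, 500, 1.5, (0.47, 0.001), (28.4, 0.001), (0.29, 0.002)),
    (5, 6.7, 233, 1.8, (0.35, 0.003), (38.0, 0.003), (0.39, 0.004)),
]

# uniform-design campaign: run, level indices, physical settings, responses
_TABLE2_LEVELS = [(5, 8, 3), (4, 1, 6), (1, 3, 4), (2, 7, 7),
                  (7, 2, 2), (8, 6, 5), (6, 4, 8), (3, 5, 1)]
_TABLE2 = [
    (1, 6.0, 550, 1.0, (0.23, 0.001), (19.3, 0.001), (0.19, 0.003)),
    (2, 5.5, 200, 1.6, (0.30, 0.002), (25.1, 0.002), (0.42, 0.004)),
    (3, 4.0, 300, 1.2, (0.69, 0.002), (51.4, 0.002), (0.54, 0.001)),
    (4, 4.5, 500, 1.8, (0.38, 0.001), (32.1, 0.001), (0.38, 0.002)),
    (5, 7.0, 250, 0.8, (0.49, 0.002), (41.2, 0.002), (0.51, 0.002)),
    (6, 7.5, 450, 1.4, (0.95, 0.001), (54.5, 0.001), (0.53, 0.003)),
    (7, 6.5, 350, 2.0, (0.83, 0.002), (69.5, 0.002), (0.61, 0.004)),
    (8, 5.0, 400, 0.6, (0.73, 0.001), (39.3, 0.001), (0.41, 0.002)),
]

# the study's own model predictions, as printed alongside the measurements
_TABLE2_PREDICTED = {
    "productivity": [0.27, 0.27, 0.68, 0.37, 0.51, 0.93, 0.86, 0.70],
    "concentration": [14.5, 30.4, 49.8, 35.6, 38.7, 56.5, 64.7, 44.3],
    "yield": [0.16, 0.40, 0.50, 0.35, 0.49, 0.51, 0.57, 0.40],
}

# published coded coefficient sets (b0, b1, b2, b3, b12, b23, b31) with
# x2 = rpm/100 and the concentration response coded as (g/L)/100
_PUBLISHED_BETA = {
    "productivity": [8.704, -0.954, -1.090, -5.477, 0.064, 0.549, 0.601],
    "concentration": [4.997, -0.518, -0.577, -3.224, 0.019, 0.333, 0.362],
    "yield": [3.749, -0.334, -0.517, -2.153, 0.021, 0.261, 0.216],
}


def _records(rows) -> list[RunRecord]:
    return [
        RunRecord(
            run_id=rid,
            settings={"pH": ph, "agitation": float(rpm), "aeration": vvm},
            responses={
                "productivity": Response(*prod),
                "concentration": Response(*conc),
                "yield": Response(*yld),
            },
        )
        for rid, ph, rpm, vvm, prod, conc, yld in rows
    ]


def table1_fixture() -> tuple[Region, list[RunRecord]]:
    """The five-run rotating-simplex campaign and its initial factor region
    (pH 4–6, 300–500 rpm, 0.5–1.5 vvm).  Run 5 is the reflection of run 3
    through the centroid of runs 1, 2 and 4."""
    region = Region({"pH": (4.0, 6.0), "agitation": (300.0, 500.0), "aeration": (0.5, 1.5)})
    return region, _records(_TABLE1)


def table2_fixture() -> tuple[DesignTable, list[RunRecord]]:
    """The exact eight-run U8(8^3) design and its measured responses."""
    design = DesignTable(
        np.array(_TABLE2_LEVELS), space=uniform_design_space(), provenance="fixture"
    )
    return design, _records(_TABLE2)


def table2_predicted() -> dict[str, np.ndarray]:
    """The study's printed model predictions for the eight uniform-design
    runs, per response, in physical units."""
    return {k: np.array(v) for k, v in _TABLE2_PREDICTED.items()}


def published_models() -> dict[str, CodedModel]:
    """The study's printed coded regression equations as CodedModel objects.

    These are the published coefficient sets, not a fresh fit of the
    packaged data (an OLS refit of the printed response means gives
    slightly different coefficients; see the methods note).  Factor ranges
    are those of the uniform-design campaign.
    """
    space = uniform_design_space()
    ranges = {f.name: (f.low, f.high) for f in space.factors}
    return {
        name: CodedModel(
            response_name=name,
            factor_names=("pH", "agitation", "aeration"),
            beta=np.array(beta),
            include_squared=False,
            coding=DEFAULT_CODING,
            factor_ranges=ranges,
        )
        for name, beta in _PUBLISHED_BETA.items()
    }
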