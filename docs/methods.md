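# Methods

This note records the statistical model, the conventions the package
commits to, the numerical choices, and what the tests do and do not
establish.

## Setting and model

A campaign varies three controllable bioreactor factors — pH (4.0–7.5,
dimensionless), agitation (200–550 rpm), aeration (0.6–2.0 vvm) — and
measures three endpoint responses per batch: xylitol productivity
(g L⁻¹ h⁻¹), xylitol concentration (g L⁻¹) and yield (g xylitol per g
xylose consumed). Each response is modelled separately by a first-order
model with pairwise interactions on a coded scale,

    y = β₀ + β₁x₁ + β₂x₂ + β₃x₃ + β₁₂x₁x₂ + β₂₃x₂x₃ + β₃₁x₃x₁ + ε,

fit by ordinary least squares. Squared terms are supported in the code but
rejected for eight-run campaigns (10 parameters > 8 runs); with the 7-term
model an 8-run design leaves a single error degree of freedom. Replicate
SDs in the packaged data are ~0.001–0.006, effectively uniform, so the fit
is unweighted.

### The coding convention (load-bearing)

All regression, ANOVA and distance computations happen on a coded scale:

| quantity      | divisor | coded value        |
|---------------|---------|--------------------|
| pH            | 1       | x₁ = pH            |
| agitation     | 100     | x₂ = rpm/100       |
| aeration      | 1       | x₃ = vvm           |
| productivity  | 1       | y₁                 |
| concentration | 100     | y₂ = (g L⁻¹)/100   |
| yield         | 1       | y₃                 |

This scheme is pinned by two facts about the packaged study: its published
productivity equation evaluated at (pH 4.3, 370 rpm, 0.9 vvm) returns the
published prediction 0.81 only with x₂ = rpm/100, and its published
concentration ANOVA total (0.19) equals the corrected SS of the measured
concentrations only after /100 response coding. Encode/decode are exact
inverses (`DEFAULT_CODING`).

## Uniform design generation

`make_uniform_design(n, s)` enumerates good-lattice-point candidates: base
columns (i·h mod n) for every h coprime to n, and the leave-one-out
variant (generate from n+1, drop the final all-(n+1) row). Every candidate
column is a permutation of 1..n. The s-column subset minimizing the
centered L2 discrepancy (Hickernell's formula on grid midpoints
(k−0.5)/n) wins; ties go to the base construction, then the
lexicographically smallest generator vector, making generation fully
deterministic.

Measured discrepancies for n = 8, s = 3: the best GLP-family design
(leave-one-out generators (1, 2, 4)) has CD2 = 0.1150; the packaged
campaign's layout — taken by its authors from published design-table
collections — has CD2 = 0.1025. The published layout is therefore *not* a
raw GLP table (no generator triple reproduces it) and is slightly more
uniform than anything the GLP family contains at this size. The generator
is validated by discrepancy optimality within its own family and by the
permutation invariant, never by cell-for-cell identity with the fixture.

## Rotating simplex

Reflection only: R_new = 2·mean(best k) − R_worst in physical units.
Out-of-bounds proposals are flagged, not clipped — the packaged campaign's
own fifth run (pH 6.7) lies outside its initial pH 4–6 range, so clipping
would misrepresent the protocol. "Worst" means the minimum of one
user-chosen response, ties broken by lowest run id. The stop rule treats
equality as no improvement: the newest run must strictly beat the best of
the k+2-run window it came from. Proposals are reported at settable
precision (pH 0.1, 1 rpm, 0.1 vvm) by the CLI; full precision is kept
internally.

## Optimization

Individual optima and the generalized-distance minimum both use an
exhaustive grid scan (defaults 0.1 pH, 10 rpm, 0.1 vvm; ~19k points)
followed by an L-BFGS-B polish from the best cell (tight tolerances,
ftol 1e-18 / gtol 1e-12, so attainable distance zeros resolve below 1e-6).
First-occurrence argmax/argmin over the lexicographically ordered grid
makes tie-breaking deterministic. The polish minimizes the smooth squared
distance, avoiding the square root's non-differentiability at zero. The
distance ρ(Y, Φ) = [Σ(Yᵢ−Φᵢ)²]^½ is computed on the coded response scale;
in raw units concentration (tens of g L⁻¹) would dominate the other two
responses outright.

Because the fitted surfaces are saddles (no interior stationary maximum),
box maxima sit on the region boundary, and their values depend strongly on
the chosen region. Over the full design box the refit surfaces' maxima
(e.g. productivity ≈ 2.35 at the pH 7.5 / 550 rpm / 2.0 vvm corner) far
exceed anything measured — honest extrapolation of a first-order model,
to be read with the extrapolation warning `predict` raises. The packaged
study's table of individual optima (0.57/55.0/0.54 at interior-like
locations) is not recoverable from its own equations over any of the
candidate regions its text states, so those values ship as data
(`PUBLISHED_INDIVIDUAL_OPTIMA`) for use as Φ targets but are never
asserted; the same holds for its simultaneous-optimum location, where the
distance function evaluates to 0.245 against a true box minimum of ≈0.035.

## Khuri–Conlon intervals

half-width = g·√MS·t_{α/2,N−p} with g = [z(ξ)ᵀ(X₀ᵀX₀)⁻¹z(ξ)]^½, X₀ the
full n×p coded model matrix of the fit and z(ξ) the p-term vector at the
optimum. Two deliberate choices: (i) √MS·t rather than a literal
(MS·t)^½ — the latter is not scale-consistent and can root a negative for
some tails; (ii) X₀ is the full 7-column model matrix (a 3-column reading
cannot pair with a 7-term z). Intervals are symmetric about Φᵢ by
construction; the packaged study's printed bounds are asymmetric and
therefore not asserted. Default α = 0.10, two-sided (t₀.₀₅,N−p). With one
error degree of freedom t is large (6.31), so intervals on the real
campaign are wide — a property of the design, not a defect.

## Refit versus published coefficients

An OLS refit of the packaged response means does not reproduce the study's
published coefficient sets (productivity β₀ = 9.072 refit vs 8.704
published; max prediction deviation 0.034 coded) — the published fit
evidently used unrounded duplicate-level data that the printed means do
not contain. Weighted fits with the printed replicate SDs and level-index
codings were tried and ruled out. Consequently:

- `fit_interaction_model` is always a fresh OLS fit of the data given;
- `published_models()` ships the published equations as data, and the
  published per-run predictions ship as `table2_predicted()`;
- the published 96.7 % concentration correlation reproduces exactly
  against the published predictions; the refit gives 97.2 %. The
  acceptance script reports the refit route (a from-scratch computation);
- one acceptance test asserting refit/published agreement at printed
  precision fails by design and documents the gap.

p-values use the exact F upper tail; the study's printed F/p pairs are
internally inconsistent with their own DF = (6, 1) and are not asserted.

## Synthetic generator

`TrueSurface` evaluates fixed coded coefficient sets and adds independent
Gaussian noise per response on the coded scale, decoded and truncated at
zero (with a flag) — truncation rather than resampling keeps each run a
pure function of its seed. Rows of a campaign use sub-seeds seed + row
index, so any row is individually reproducible. Defaults: the published
coefficient sets as ground truth and noise_sd = 0.01 coded units per
response, slightly above the real campaign's replicate SDs (≤ 0.006).

What it emulates: the saddle-shaped linear+interaction response structure
over the factor box, replicate-level measurement noise, non-negativity.
What it does not: fermentation kinetics or time courses, factor-setting
error, heteroscedastic or correlated-between-response noise, model
misspecification (the generator's truth lies inside the fitted model
class). Passing recovery tests therefore demonstrate the estimator and
optimizer are correct and unbiased *under the model*, not that the model
suits any particular organism.

## Problem sizes and determinism

All analyses are desk scale: 8-run designs, 7-parameter fits, ~19k-point
grids, a 200-replicate Monte-Carlo calibration (mean coefficient within 3
empirical standard errors of truth), and a 10,000-point random sample as
the grid-oracle check; the full suite runs in a few seconds. Property
tests run hypothesis derandomised; every stochastic component takes an
explicit seed; pipeline reports are byte-identical across reruns on
identical inputs.

## Known limitations

- First-order + interaction surfaces cannot represent interior optima;
  conclusions about "optimal" settings are region-relative.
- Eight runs leave one error degree of freedom: F tests and interval
  widths are fragile, and ANOVA p-values should be read qualitatively.
- The generalized distance weights responses equally on the coded scale;
  no preference weighting (e.g. desirability functions) is provided.
- The simplex module implements reflection only, matching the protocol it
  reproduces, not full Nelder–Mead.
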