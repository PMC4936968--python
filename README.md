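# fermopt

Design-of-experiments and multi-response optimization for small bioreactor
fermentation campaigns.

Bioprocess optimization studies — here, xylitol production from xylose by
the yeast *Debaryomyces nepalensis* in a stirred-tank reactor — must find
good settings of a few controllable factors (pH, agitation speed in rpm,
aeration rate in vvm) for several competing responses at once
(productivity in g L⁻¹ h⁻¹, product concentration in g L⁻¹, yield in
g g⁻¹), with each experiment costing a multi-day batch fermentation.
`fermopt` implements the complete desk workflow such a campaign uses:

- **Uniform designs** U_n(n^s) by the number-theoretic good-lattice-point
  method: candidate columns (i·h_k mod n) for generators h_k coprime to n
  (plus the leave-one-out construction from n+1), ranked by centered L2
  discrepancy, so n runs cover an n-level grid as evenly as possible.
- **Rotating-simplex protocol** for sequential experiments: the worst of
  k+1 runs is replaced by its reflection through the centroid of the rest,
  R_new = 2·mean(best k) − R_worst, until improvement stops.
- **Coded interaction regression** by OLS,
  y = β₀ + Σᵢ βᵢxᵢ + Σᵢ<ⱼ βᵢⱼxᵢxⱼ, with ANOVA (regression/error/total
  sums of squares, F, p) and observed-vs-predicted percentage correlation.
  Coding (x₂ = rpm/100, concentration/100) keeps coefficients comparable.
- **Multi-response optimization** by the generalized distance approach:
  individual box-constrained optima Φᵢ per response, then the operating
  point minimizing ρ(Y(x), Φ) = [Σᵢ (Yᵢ(x) − Φᵢ)²]^½ on the coded scale.
- **Khuri–Conlon rectangular confidence intervals** around individual
  optima: half-width = [z(ξ)ᵀ(X₀ᵀX₀)⁻¹z(ξ)]^½ · √MSᵢ · t_{α/2,N−p}.
- **Synthetic campaign generator** (known interaction surfaces + coded
  Gaussian noise) so every stage is testable without wet-lab data.

The packaged datasets are the printed records of a published optimization
campaign (a five-run simplex sequence and an eight-run U₈(8³) table with
duplicate-averaged responses), together with that study's published
regression equations and baselines.

## Worked example

Fit the three coded response models to the packaged eight-run campaign
(`python examples/fit_and_anova.py`):

```
productivity:
  coded coefficients (b0, b1, b2, b3, b12, b23, b31):
    9.072, -1.001, -1.167, -5.563, 0.074, 0.565, 0.605
  ANOVA  DF (reg, err, tot) = (6, 1, 7)  SS = (0.48, 0.00, 0.48)  F = 19.94  p = 0.17
  percentage correlation (obs vs refit): 99.6 %
...
concentration correlation vs the campaign's published predictions: 96.7 %
```

The large |b₃| (aeration) and b₂₃ (agitation×aeration) terms say oxygen
supply dominates xylitol formation; the corrected total SS (0.48, 0.19,
0.12 on the coded scale) match the campaign's published ANOVA. Then
optimize all three responses at once
(`python examples/multi_response_optimization.py`):

```
Published equations at the study's reported operating point (pH 4.3, 370 rpm, 0.9 vvm):
  productivity: 0.81  (+88.79 % vs baseline 0.43)
  concentration: 54.52  (+0.97 % vs baseline 54.0)
  yield: 0.50  (-21.66 % vs baseline 0.64)
```

i.e. the published equations predict 0.81 g L⁻¹ h⁻¹ productivity at the
study's simultaneous optimum, an ~89 % gain over the prior fixed-condition
reactor baseline at a small cost in yield. The other examples cover design
construction (`uniform_design.py`), the sequential simplex replay
(`simplex_campaign.py`) and synthetic parameter recovery
(`synthetic_recovery.py`). A thin CLI wraps the same functions:

```sh
fermopt design uniform --runs 8 --factor pH:4:7.5:8 \
  --factor agitation:200:550:8 --factor aeration:0.6:2.0:8 -o design.csv
fermopt simplex next --runs runs.csv --response concentration
fermopt fit --data table2.csv --response productivity -o models/productivity.txt
fermopt optimize --models models/ --region pH:4:7.5,agitation:200:550,aeration:0.6:2.0
fermopt report --data table2.csv --region pH:4:7.5,agitation:200:550,aeration:0.6:2.0
```

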